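"""Enumeration and classification of the single-nucleotide substitution space of a CDS.

Every position of a coding sequence admits exactly three alternate bases, so a
CDS of enumerated length L has 3L possible nucleotide variants.  Each variant
maps to one amino acid change (possibly synonymous); distinct amino acid
changes are the deduplicated set of (codon index, alternate residue) pairs.
Coverage statistics compare an observed variant set against this theoretical
space.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError

BASES = ("A", "C", "G", "T")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

# Standard genetic code, first codon base varying slowest over TCAG.
_AA_ORDER = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE: dict[str, str] = {
    "".join(codon): aa
    for codon, aa in zip(itertools.product("TCAG", repeat=3), _AA_ORDER)
}
STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")

EFFECT_CLASSES = ("synonymous", "missense", "nonsense", "stop_altering")


def translate_codon(codon: str) -> str:
    """Translate a trinucleotide under the standard genetic code ('*' = stop)."""
    try:
        return CODON_TABLE[codon]
    except KeyError:
        raise ValidationError(f"not a valid codon: {codon!r}") from None


def classify_substitution(ref_base: str, alt_base: str) -> str:
    """Classify a base substitution as 'transition' or 'transversion'."""
    if ref_base not in BASES or alt_base not in BASES:
        raise ValidationError(
            f"bases must be one of {BASES}, got {ref_base!r}->{alt_base!r}"
        )
    if ref_base == alt_base:
        raise ValidationError(f"ref and alt base are identical: {ref_base!r}")
    same_class = ({ref_base, alt_base} <= _PURINES) or (
        {ref_base, alt_base} <= _PYRIMIDINES
    )
    return "transition" if same_class else "transversion"


def classify_effect(ref_aa: str, alt_aa: str) -> str:
    """Effect class of an amino acid change.

    A change away from the terminal stop is ``stop_altering``; a stop-to-stop
    substitution is treated as synonymous.
    """
    if ref_aa == "*":
        return "synonymous" if alt_aa == "*" else "stop_altering"
    if alt_aa == "*":
        return "nonsense"
    return "synonymous" if ref_aa == alt_aa else "missense"


@dataclass(frozen=True)
class CodingSequence:
    """A validated in-frame coding sequence over {A, C, G, T}.

    Parameters
    ----------
    id : str
        Record label.
    sequence : str
        The CDS, 5'->3' sense strand; length must be a positive multiple of 3.
    includes_stop : bool
        Whether the final codon is a stop codon.  When True the terminal codon
        must translate to stop and no internal codon may.
    """

    id: str
    sequence: str
    includes_stop: bool = True

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) == 0 or len(seq) % 3 != 0:
            raise ValidationError(
                f"CDS {self.id!r}: length {len(seq)} is not a positive multiple of 3"
            )
        for i, base in enumerate(seq, start=1):
            if base not in BASES:
                raise ValidationError(
                    f"CDS {self.id!r}: invalid base {base!r} at position {i}"
                )
        if self.includes_stop:
            codons = self.codons
            if translate_codon(codons[-1]) != "*":
                raise ValidationError(
                    f"CDS {self.id!r}: includes_stop is set but final codon "
                    f"{codons[-1]} is not a stop codon"
                )
            for ci, codon in enumerate(codons[:-1], start=1):
                if translate_codon(codon) == "*":
                    raise ValidationError(
                        f"CDS {self.id!r}: internal stop codon at codon {ci}"
                    )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_codons(self) -> int:
        return self.length // 3

    @property
    def codons(self) -> tuple[str, ...]:
        s = self.sequence
        return tuple(s[i : i + 3] for i in range(0, len(s), 3))

    def protein(self) -> str:
        """Translated protein, including '*' for a terminal stop."""
        return "".join(translate_codon(c) for c in self.codons)

    @classmethod
    def from_fasta(cls, path: str | Path, includes_stop: bool | None = None) -> "CodingSequence":
        """Load a CDS from a single-record FASTA file.

        ``includes_stop=None`` infers the flag from the final codon.
        """
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) == 0:
            raise ValidationError(f"{path}: no FASTA records found")
        if len(records) > 1:
            raise ValidationError(
                f"{path}: expected a single FASTA record, found {len(records)}"
            )
        rec = records[0]
        seq = str(rec.seq).upper()
        if includes_stop is None:
            includes_stop = len(seq) >= 3 and len(seq) % 3 == 0 and seq[-3:] in STOP_CODONS
        return cls(id=rec.id, sequence=seq, includes_stop=includes_stop)


@dataclass(frozen=True)
class NucleotideVariant:
    """One single-nucleotide substitution on a CDS (1-based coordinates)."""

    position: int
    ref_base: str
    alt_base: str
    codon_index: int
    ref_codon: str
    alt_codon: str
    subst_class: str

    def __post_init__(self):
        if self.ref_base == self.alt_base:
            raise ValidationError(
                f"variant at position {self.position}: ref equals alt ({self.ref_base})"
            )
        diffs = sum(a != b for a, b in zip(self.ref_codon, self.alt_codon))
        if diffs != 1:
            raise ValidationError(
                f"variant at position {self.position}: codons {self.ref_codon}/"
                f"{self.alt_codon} differ at {diffs} positions, expected 1"
            )

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref_base, self.alt_base)


@dataclass(frozen=True)
class AminoAcidChange:
    """An amino acid level change reachable by a single substitution."""

    codon_index: int
    ref_aa: str
    alt_aa: str
    effect: str

    @property
    def key(self) -> tuple[int, str]:
        return (self.codon_index, self.alt_aa)

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.codon_index}{self.alt_aa}"


def make_variant(cds: CodingSequence, position: int, alt_base: str) -> NucleotideVariant:
    """Build a validated variant at a 1-based CDS position."""
    if not 1 <= position <= cds.length:
        raise ValidationError(
            f"position {position} outside CDS {cds.id!r} (length {cds.length})"
        )
    ref_base = cds.sequence[position - 1]
    codon_index = (position - 1) // 3 + 1
    ref_codon = cds.codons[codon_index - 1]
    offset = (position - 1) % 3
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
    return NucleotideVariant(
        position=position,
        ref_base=ref_base,
        alt_base=alt_base,
        codon_index=codon_index,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        subst_class=classify_substitution(ref_base, alt_base),
    )


def aa_change_for(variant: NucleotideVariant) -> AminoAcidChange:
    """The amino acid change induced by a nucleotide variant."""
    ref_aa = translate_codon(variant.ref_codon)
    alt_aa = translate_codon(variant.alt_codon)
    return AminoAcidChange(
        codon_index=variant.codon_index,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        effect=classify_effect(ref_aa, alt_aa),
    )


@dataclass
class VariantSpace:
    """The exhaustive single-substitution catalogue of a CDS.

    ``nt_variants`` and ``changes`` are aligned; ``aa_changes`` maps each
    distinct (codon_index, alt_aa) pair to its effect class.
    """

    cds_id: str
    enumerated_length: int
    nt_variants: tuple[NucleotideVariant, ...]
    changes: tuple[AminoAcidChange, ...]
    aa_changes: dict[tuple[int, str], str]
    nt_counts: Counter = field(default_factory=Counter)
    aa_counts: Counter = field(default_factory=Counter)
    _nt_keys: frozenset = field(default=frozenset(), repr=False)
    _by_key: dict = field(default_factory=dict, repr=False)

    @property
    def n_nt(self) -> int:
        return len(self.nt_variants)

    @property
    def n_aa_coding(self) -> int:
        """Distinct missense + nonsense amino acid changes."""
        return self.aa_counts["missense"] + self.aa_counts["nonsense"]

    def contains_nt(self, key: tuple[int, str, str]) -> bool:
        return key in self._nt_keys

    def change_for(self, key: tuple[int, str, str]) -> AminoAcidChange:
        return self._by_key[key]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "pos": v.position,
                "ref": v.ref_base,
                "alt": v.alt_base,
                "codon_index": v.codon_index,
                "ref_codon": v.ref_codon,
                "alt_codon": v.alt_codon,
                "ref_aa": c.ref_aa,
                "alt_aa": c.alt_aa,
                "effect": c.effect,
                "subst_class": v.subst_class,
            }
            for v, c in zip(self.nt_variants, self.changes)
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "cds_id": self.cds_id,
            "enumerated_length": self.enumerated_length,
            "n_nt_variants": self.n_nt,
            "n_aa_changes": len(self.aa_changes),
            "n_aa_coding_changes": self.n_aa_coding,
            "nt_counts": dict(self.nt_counts),
            "aa_counts": dict(self.aa_counts),
        }


def enumerate_snv_space(cds: CodingSequence, include_stop_codon: bool = False) -> VariantSpace:
    """Enumerate all 3L single-nucleotide substitutions of a CDS.

    When the CDS carries a terminal stop codon and ``include_stop_codon`` is
    False, the final three bases are excluded from enumeration.  Variants of
    an included stop codon are classed ``stop_altering`` (or synonymous for
    stop-to-stop substitutions) and never count toward missense/nonsense
    totals.
    """
    length = cds.length
    if cds.includes_stop and not include_stop_codon:
        length -= 3

    variants: list[NucleotideVariant] = []
    changes: list[AminoAcidChange] = []
    aa_changes: dict[tuple[int, str], str] = {}
    nt_counts: Counter = Counter()
    aa_counts: Counter = Counter()

    for pos in range(1, length + 1):
        ref = cds.sequence[pos - 1]
        for alt in BASES:
            if alt == ref:
                continue
            v = make_variant(cds, pos, alt)
            c = aa_change_for(v)
            variants.append(v)
            changes.append(c)
            nt_counts[c.effect] += 1
            if c.key not in aa_changes:
                aa_changes[c.key] = c.effect
                aa_counts[c.effect] += 1

    return VariantSpace(
        cds_id=cds.id,
        enumerated_length=length,
        nt_variants=tuple(variants),
        changes=tuple(changes),
        aa_changes=aa_changes,
        nt_counts=nt_counts,
        aa_counts=aa_counts,
        _nt_keys=frozenset(v.key for v in variants),
        _by_key={v.key: c for v, c in zip(variants, changes)},
    )


@dataclass(frozen=True)
class SpectrumTable:
    """Counts of the 12 ordered base substitutions with class marginals."""

    counts: Mapping[tuple[str, str], int]

    def __post_init__(self):
        for (r, a), n in self.counts.items():
            if n < 0:
                raise ValidationError(f"negative count for {r}->{a}: {n}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def transitions(self) -> int:
        return sum(
            n
            for (r, a), n in self.counts.items()
            if classify_substitution(r, a) == "transition"
        )

    @property
    def transversions(self) -> int:
        return self.total - self.transitions

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "ref": r,
                "alt": a,
                "count": self.counts.get((r, a), 0),
                "subst_class": classify_substitution(r, a),
            }
            for r in BASES
            for a in BASES
            if r != a
        ]
        return pd.DataFrame(rows)


def spectrum_table(variants: Iterable[NucleotideVariant]) -> SpectrumTable:
    """Tabulate the ordered substitution spectrum of a variant collection."""
    counts: Counter = Counter()
    for r in BASES:
        for a in BASES:
            if r != a:
                counts[(r, a)] = 0
    for v in variants:
        counts[(v.ref_base, v.alt_base)] += 1
    return SpectrumTable(counts=dict(counts))


def coverage_percent(n_observed: int, n_possible: int) -> float:
    """Percentage of a variant space covered, reported to one decimal."""
    if n_possible <= 0:
        raise ValidationError(f"possible-variant count must be positive, got {n_possible}")
    if n_observed < 0:
        raise ValidationError(f"observed count must be non-negative, got {n_observed}")
    return round(100.0 * n_observed / n_possible, 1)


@dataclass
class CoverageSummary:
    """Observed-versus-theoretical coverage at nucleotide and amino acid level."""

    n_nt_observed: int
    n_nt_possible: int
    nt_percent: float
    n_aa_observed: int
    n_aa_possible: int
    aa_percent: float
    rejects: list[str] = field(default_factory=list)


def library_coverage(
    observed_nt: Iterable[NucleotideVariant],
    observed_aa: Iterable[AminoAcidChange] | None,
    space: VariantSpace,
) -> CoverageSummary:
    """Coverage of the theoretical space by observed variant sets.

    Nucleotide coverage counts unique observed variants over 3L; amino acid
    coverage counts distinct missense/nonsense changes over the theoretical
    missense+nonsense total.  Observations absent from the space are reported
    in ``rejects``, never silently dropped.  ``observed_aa=None`` derives the
    amino acid set from the nucleotide set.
    """
    rejects: list[str] = []
    nt_keys: set[tuple[int, str, str]] = set()
    for v in observed_nt:
        if space.contains_nt(v.key):
            nt_keys.add(v.key)
        else:
            rejects.append(
                f"nt variant {v.position}{v.ref_base}>{v.alt_base} not in space"
            )

    if observed_aa is None:
        aa_iter = [space.change_for(k) for k in nt_keys]
    else:
        aa_iter = list(observed_aa)

    aa_keys: set[tuple[int, str]] = set()
    for c in aa_iter:
        known = space.aa_changes.get(c.key)
        if known is None:
            rejects.append(f"aa change {c} not in space")
        elif known in ("missense", "nonsense"):
            aa_keys.add(c.key)

    return CoverageSummary(
        n_nt_observed=len(nt_keys),
        n_nt_possible=space.n_nt,
        nt_percent=coverage_percent(len(nt_keys), space.n_nt),
        n_aa_observed=len(aa_keys),
        n_aa_possible=space.n_aa_coding,
        aa_percent=coverage_percent(len(aa_keys), space.n_aa_coding),
        rejects=rejects,
    )


def expected_coding_changes_per_insert(
    nt_rate: float,
    space: VariantSpace | tuple[int, int],
) -> float:
    """Expected number of amino-acid-changing variants per mutagenized insert.

    ``nt_rate`` is the mean nucleotide substitutions per insert; the result is
    ``nt_rate`` times the fraction of the nucleotide space whose distinct
    amino acid outcomes are missense or nonsense.  ``space`` may be a
    VariantSpace or an explicit ``(n_aa_coding, n_nt)`` pair.
    """
    if nt_rate < 0:
        raise ValidationError(f"nt_rate must be non-negative, got {nt_rate}")
    if isinstance(space, VariantSpace):
        n_coding, n_nt = space.n_aa_coding, space.n_nt
    else:
        n_coding, n_nt = space
    if n_nt <= 0:
        raise ValidationError("empty variant space")
    return nt_rate * n_coding / n_nt
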