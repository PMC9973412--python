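"""Tabular interchange formats: per-variant count tables, results, manifests.

The count-table dialect is a TSV with header
``pos\tref\talt\tvariant_reads\tlocus_total_reads`` — one row per
(position, alternate base) per sample, with the aligned-read total at that
locus.  Readers reject invalid data with the offending row number; they never
repair it.  Frequencies are always recomputed from counts downstream, never
trusted from files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import pandas as pd
import yaml

from .errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .enrichment import EnrichmentRecord
    from .variant_space import CodingSequence, NucleotideVariant

_BASES = frozenset("ACGT")
COUNT_COLUMNS = ("pos", "ref", "alt", "variant_reads", "locus_total_reads")
RESULT_COLUMNS = (
    "pos", "ref", "alt", "aa_change", "freq_library", "freq_timepoint",
    "fold_change", "p", "q", "hit",
)


class VariantCountTable:
    """Validated per-sample variant read counts.

    Wraps a DataFrame with columns ``pos, ref, alt, variant_reads,
    locus_total_reads``.  Invariants enforced on construction:
    ``0 <= variant_reads <= locus_total_reads``; one row per (pos, alt);
    a single locus total per position.
    """

    def __init__(self, sample_id: str, frame: pd.DataFrame, _row_offset: int = 0):
        missing = [c for c in COUNT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"count table missing columns: {missing}")
        frame = frame.loc[:, list(COUNT_COLUMNS)].reset_index(drop=True)

        def rownum(i: int) -> int:
            return i + 1 + _row_offset

        try:
            frame["pos"] = frame["pos"].astype(int)
            frame["variant_reads"] = frame["variant_reads"].astype(int)
            frame["locus_total_reads"] = frame["locus_total_reads"].astype(int)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"count table has non-integer counts: {exc}") from exc

        for i, row in enumerate(frame.itertuples(index=False)):
            if row.ref not in _BASES or row.alt not in _BASES:
                raise ValidationError(
                    f"row {rownum(i)}: invalid base {row.ref!r}/{row.alt!r}"
                )
            if row.ref == row.alt:
                raise ValidationError(f"row {rownum(i)}: ref equals alt ({row.ref})")
            if row.pos < 1:
                raise ValidationError(f"row {rownum(i)}: position {row.pos} < 1")
            if row.variant_reads < 0:
                raise ValidationError(
                    f"row {rownum(i)}: negative variant_reads {row.variant_reads}"
                )
            if row.variant_reads > row.locus_total_reads:
                raise ValidationError(
                    f"row {rownum(i)}: variant_reads {row.variant_reads} exceeds "
                    f"locus_total_reads {row.locus_total_reads}"
                )

        dup = frame.duplicated(subset=["pos", "alt"])
        if dup.any():
            i = int(dup.idxmax())
            raise ValidationError(
                f"row {rownum(i)}: duplicate (pos, alt) = "
                f"({frame.at[i, 'pos']}, {frame.at[i, 'alt']})"
            )
        per_pos = frame.groupby("pos")["locus_total_reads"].nunique()
        bad = per_pos[per_pos > 1]
        if len(bad):
            raise ValidationError(
                f"inconsistent locus_total_reads at positions {list(bad.index)}"
            )
        per_pos_ref = frame.groupby("pos")["ref"].nunique()
        bad = per_pos_ref[per_pos_ref > 1]
        if len(bad):
            raise ValidationError(
                f"inconsistent ref base at positions {list(bad.index)}"
            )

        self.sample_id = sample_id
        self._frame = frame.sort_values(["pos", "alt"], kind="mergesort").reset_index(
            drop=True
        )

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def __len__(self) -> int:
        return len(self._frame)

    def frequencies(self) -> pd.Series:
        f = self._frame
        if (f["locus_total_reads"] == 0).any():
            raise ValidationError("zero locus_total_reads: frequency undefined")
        return f["variant_reads"] / f["locus_total_reads"]

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str | None = None) -> "VariantCountTable":
        path = Path(path)
        try:
            frame = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str})
        except Exception as exc:
            raise ValidationError(f"{path}: cannot parse TSV: {exc}") from exc
        # +1 for the header line so reported row numbers match the file
        return cls(sample_id or path.stem, frame, _row_offset=1)

    def to_tsv(self, path: str | Path) -> None:
        self._frame.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path, sample_id: str | None = None) -> VariantCountTable:
    """Read and validate a variant count TSV."""
    return VariantCountTable.from_tsv(path, sample_id=sample_id)


def write_results(records: Iterable["EnrichmentRecord"], path: str | Path) -> None:
    """Write enrichment records as a results TSV.

    Floats are rendered with six significant digits; rows are ordered by
    (position, alt).  An empty record set produces a header-only file.
    """
    rows = [
        {
            "pos": r.position,
            "ref": r.ref,
            "alt": r.alt,
            "aa_change": r.aa_change,
            "freq_library": r.freq_library,
            "freq_timepoint": r.freq_timepoint,
            "fold_change": r.fold_change,
            "p": r.p_value,
            "q": r.q_value,
            "hit": r.hit,
        }
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(frame):
        frame = frame.sort_values(["pos", "alt"], kind="mergesort")
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results TSV back into a DataFrame."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"results table missing columns: {missing}")
    return frame


def read_annotated_variants(
    path: str | Path,
    cds: "CodingSequence",
    dialect: str = "minimal",
) -> set["NucleotideVariant"]:
    """Read an annotated-variant table into a set of validated variants.

    ``minimal`` expects columns pos/ref/alt; ``annovar_like`` is a tolerant
    dialect accepting Start/Ref/Alt (any case) among arbitrary extra columns.
    Coordinates must fall within the CDS and the reference base must match.
    """
    from .variant_space import make_variant

    if dialect not in ("minimal", "annovar_like"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    frame = pd.read_csv(path, sep="\t", dtype=str)

    if dialect == "minimal":
        colmap = {"pos": "pos", "ref": "ref", "alt": "alt"}
    else:
        lower = {c.lower(): c for c in frame.columns}
        colmap = {}
        for want, names in (
            ("pos", ("start", "pos", "position")),
            ("ref", ("ref", "ref_base")),
            ("alt", ("alt", "alt_base")),
        ):
            for n in names:
                if n in lower:
                    colmap[want] = lower[n]
                    break
    missing = [k for k in ("pos", "ref", "alt") if k not in colmap or colmap[k] not in frame.columns]
    if missing:
        raise ValidationError(f"annotated-variant table missing columns: {missing}")

    pos_col, ref_col, alt_col = colmap["pos"], colmap["ref"], colmap["alt"]
    out: set = set()
    for offset in range(len(frame)):
        i = offset + 2  # file row number (1 header line)
        try:
            pos = int(frame[pos_col].iloc[offset])
        except (ValueError, TypeError):
            raise ValidationError(
                f"row {i}: non-integer position {frame[pos_col].iloc[offset]!r}"
            ) from None
        ref = str(frame[ref_col].iloc[offset]).upper()
        alt = str(frame[alt_col].iloc[offset]).upper()
        if not 1 <= pos <= cds.length:
            raise ValidationError(f"row {i}: position {pos} outside CDS (length {cds.length})")
        v = make_variant(cds, pos, alt)
        if v.ref_base != ref:
            raise ValidationError(
                f"row {i}: reference base {ref} does not match CDS base {v.ref_base} "
                f"at position {pos}"
            )
        out.add(v)
    return out


@dataclass(frozen=True)
class TimepointSample:
    sample_id: str
    day: int
    path: Path


@dataclass
class SampleManifest:
    """Screen manifest: one library sample, ordered timepoints, thresholds."""

    cds_fasta: Path
    library_id: str
    library_path: Path
    timepoints: tuple[TimepointSample, ...]
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.timepoints:
            raise ValidationError("manifest must list at least one timepoint sample")


def load_manifest(path: str | Path) -> SampleManifest:
    """Load a YAML/JSON screen manifest; paths resolve relative to the file."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: manifest must be a mapping")
    base = path.parent

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    try:
        library = data["library"]
        timepoints = data["timepoints"]
        cds_fasta = resolve(data["cds_fasta"])
    except KeyError as exc:
        raise ValidationError(f"{path}: manifest missing key {exc}") from exc
    if isinstance(library, list):
        raise ValidationError(f"{path}: exactly one library sample is required")
    tps = tuple(
        TimepointSample(
            sample_id=str(t.get("id", f"day{t['day']}")),
            day=int(t["day"]),
            path=resolve(t["path"]),
        )
        for t in timepoints
    )
    return SampleManifest(
        cds_fasta=cds_fasta,
        library_id=str(library.get("id", "library")),
        library_path=resolve(library["path"]),
        timepoints=tps,
        params=dict(data.get("params", {})),
    )
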