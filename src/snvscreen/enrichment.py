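"""Per-variant enrichment scoring: frequencies, fold changes, hit calling.

A variant's frequency is its read count over the total reads aligned at the
same locus; enrichment is the timepoint frequency over the library frequency.
Significance uses the exact conditional test on the 2x2 table
[variant vs other reads] x [library vs timepoint], valid at the extreme FDR
tail where normal approximations fail; Benjamini-Hochberg controls the FDR
across all assessable variants.  Only variants observed in both samples are
assessable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

from .counts_io import VariantCountTable
from .errors import ValidationError
from .variant_space import VariantSpace, coverage_percent

__all__ = [
    "EnrichmentRecord",
    "HitCallParams",
    "FoldChangePolicy",
    "ScreenResult",
    "variant_frequency",
    "fold_change",
    "fold_change_from_counts",
    "enrichment_test",
    "adjust_bh",
    "score_screen",
    "call_hits",
    "compare_screens",
    "screen_report",
]


def variant_frequency(variant_reads: int, locus_total_reads: int) -> float:
    """Reads carrying a variant over total aligned reads at the locus."""
    if locus_total_reads == 0:
        raise ValidationError("locus_total_reads is 0: frequency undefined")
    if not 0 <= variant_reads <= locus_total_reads:
        raise ValidationError(
            f"variant_reads {variant_reads} outside [0, {locus_total_reads}]"
        )
    return variant_reads / locus_total_reads


@dataclass(frozen=True)
class FoldChangePolicy:
    """Continuity handling for zero library counts.

    ``pseudocount`` is added to the variant read count in both samples before
    forming the ratio.  ``strict=True`` instead excludes zero-library
    variants (fold change is None for them).
    """

    pseudocount: float = 0.5
    strict: bool = False


def fold_change(freq_timepoint: float, freq_library: float) -> float:
    """Plain frequency ratio; equal inputs give exactly 1.0."""
    for name, f in (("timepoint", freq_timepoint), ("library", freq_library)):
        if not 0 <= f <= 1:
            raise ValidationError(f"{name} frequency {f} outside [0, 1]")
    if freq_library == 0:
        raise ValidationError(
            "library frequency is 0; use fold_change_from_counts with a "
            "pseudocount policy, or exclude the variant under strict policy"
        )
    if freq_timepoint == freq_library:
        return 1.0
    return freq_timepoint / freq_library


def fold_change_from_counts(
    tp_reads: int,
    tp_total: int,
    lib_reads: int,
    lib_total: int,
    policy: FoldChangePolicy = FoldChangePolicy(),
) -> float | None:
    """Fold change from raw counts under a pseudocount policy.

    Returns None for zero-library variants under the strict policy (the
    excluded-variant signal, not an error).
    """
    if tp_total <= 0 or lib_total <= 0:
        raise ValidationError("locus totals must be positive")
    if policy.strict:
        if lib_reads == 0:
            return None
        return variant_frequency(tp_reads, tp_total) / variant_frequency(
            lib_reads, lib_total
        )
    c = policy.pseudocount
    return ((tp_reads + c) / tp_total) / ((lib_reads + c) / lib_total)


def _fisher_two_sided(a: int, n1: int, b: int, n2: int) -> float:
    """Exact conditional two-sided p for the 2x2 table [[a, n1-a], [b, n2-b]].

    Conditional on margins, the timepoint variant count is hypergeometric;
    the two-sided p sums every outcome whose probability does not exceed the
    observed one (with the customary (1 + 1e-7) tolerance for float ties).
    """
    k_total = a + b
    n_total = n1 + n2
    lo = max(0, k_total - n1)
    hi = min(k_total, n2)
    support = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(k_total + 1)
        - gammaln(support + 1)
        - gammaln(k_total - support + 1)
        + gammaln(n_total - k_total + 1)
        - gammaln(n2 - support + 1)
        - gammaln(n_total - k_total - n2 + support + 1)
        - (gammaln(n_total + 1) - gammaln(n2 + 1) - gammaln(n_total - n2 + 1))
    )
    observed = logpmf[b - lo]
    keep = logpmf <= observed + 1e-7
    return float(min(1.0, np.exp(logsumexp(logpmf[keep]))))


def _normal_two_sided(a: int, n1: int, b: int, n2: int) -> float:
    """Two-proportion z-test (pooled variance), two-sided."""
    p1, p2 = a / n1, b / n2
    pooled = (a + b) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        return 1.0
    z = (p2 - p1) / np.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


def enrichment_test(
    lib_counts: tuple[int, int],
    tp_counts: tuple[int, int],
    method: str = "exact",
) -> float:
    """Two-sided p for a difference in variant proportions.

    ``lib_counts``/``tp_counts`` are (variant_reads, locus_total_reads)
    pairs.  ``method='exact'`` is the exact conditional test on the 2x2
    table; ``'normal'`` is a two-proportion z approximation for speed at
    high depth.
    """
    a, n1 = lib_counts
    b, n2 = tp_counts
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("zero locus totals: test undefined")
    if not (0 <= a <= n1 and 0 <= b <= n2):
        raise ValidationError("variant reads outside [0, total]")
    if method == "exact":
        return _fisher_two_sided(a, n1, b, n2)
    if method == "normal":
        return _normal_two_sided(a, n1, b, n2)
    raise ValidationError(f"unknown test method {method!r}")


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotone enforcement.

    Stable under permutation of the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        bad = p[(p < 0) | (p > 1) | ~np.isfinite(p)]
        raise ValidationError(f"p-values outside [0, 1]: {bad[:5]}")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


@dataclass(frozen=True)
class HitCallParams:
    """Hit thresholds: minimum fold change, maximum q, library-read floor."""

    min_fold_change: float = 50.0
    max_q: float = 0.00001
    min_library_reads: int = 1

    def __post_init__(self):
        if self.min_fold_change <= 0:
            raise ValidationError("min_fold_change must be positive")
        if not 0 < self.max_q < 1:
            raise ValidationError("max_q must be in (0, 1)")


# Preset matching the replicate screen's published cutoff.
REPLICATE_SCREEN_PARAMS = HitCallParams(min_fold_change=47.0)


@dataclass
class EnrichmentRecord:
    """One variant's scoring record across library and timepoint."""

    position: int
    ref: str
    alt: str
    codon_index: int
    ref_aa: str
    alt_aa: str
    effect: str
    freq_library: float
    freq_timepoint: float
    fold_change: float
    p_value: float
    q_value: float
    hit: bool
    lib_reads: int = 0
    tp_reads: int = 0

    @property
    def aa_change(self) -> str:
        return f"{self.ref_aa}{self.codon_index}{self.alt_aa}"


def call_hits(
    records: Iterable[EnrichmentRecord], params: HitCallParams
) -> tuple[list[EnrichmentRecord], int, int]:
    """Apply thresholds, returning (records, n_hits, n_passengers).

    A hit satisfies fold change >= min_fold_change and q < max_q with at
    least ``min_library_reads`` library reads; everything else is a
    passenger.
    """
    records = list(records)
    n_hits = 0
    for r in records:
        r.hit = (
            r.fold_change >= params.min_fold_change
            and r.q_value < params.max_q
            and r.lib_reads >= params.min_library_reads
        )
        n_hits += r.hit
    return records, n_hits, len(records) - n_hits


@dataclass
class ScreenResult:
    """Scored screen: records plus assessable-set size and space coverage."""

    records: list[EnrichmentRecord]
    n_assessable: int
    n_hits: int
    n_passengers: int
    coverage_aa_percent: float
    params: HitCallParams
    rejects: list[str] = field(default_factory=list)
    status: str = "ok"

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "pos": r.position,
                "ref": r.ref,
                "alt": r.alt,
                "aa_change": r.aa_change,
                "codon_index": r.codon_index,
                "effect": r.effect,
                "freq_library": r.freq_library,
                "freq_timepoint": r.freq_timepoint,
                "fold_change": r.fold_change,
                "p": r.p_value,
                "q": r.q_value,
                "hit": r.hit,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)


def score_screen(
    library: VariantCountTable,
    timepoint: VariantCountTable,
    space: VariantSpace,
    params: HitCallParams = HitCallParams(),
    policy: FoldChangePolicy = FoldChangePolicy(),
    test_method: str = "exact",
) -> ScreenResult:
    """Score one timepoint against the plasmid library.

    Only variants observed (>= 1 read, and >= ``params.min_library_reads``
    in the library) in *both* samples enter scoring; observations outside
    the variant space are reported in ``rejects``.  q-values are BH-adjusted
    across the assessable family; hits satisfy the fold-change and q
    thresholds.  The result is invariant to input row order.
    """
    lib = library.frame
    tp = timepoint.frame
    merged = lib.merge(
        tp, on=["pos", "ref", "alt"], how="inner", suffixes=("_lib", "_tp")
    )
    merged = merged[
        (merged["variant_reads_lib"] >= max(1, params.min_library_reads))
        & (merged["variant_reads_tp"] >= 1)
    ]

    rejects: list[str] = []
    keep = []
    for i, row in enumerate(merged.itertuples(index=False)):
        key = (row.pos, row.ref, row.alt)
        if space.contains_nt(key):
            keep.append(i)
        else:
            rejects.append(f"variant {row.pos}{row.ref}>{row.alt} not in variant space")
    merged = merged.iloc[keep].sort_values(["pos", "alt"], kind="mergesort")

    if len(merged) == 0:
        warnings.warn("no assessable variants shared between library and timepoint")
        return ScreenResult(
            records=[],
            n_assessable=0,
            n_hits=0,
            n_passengers=0,
            coverage_aa_percent=0.0,
            params=params,
            rejects=rejects,
            status="empty",
        )

    records: list[EnrichmentRecord] = []
    p_values = []
    for row in merged.itertuples(index=False):
        a, n1 = int(row.variant_reads_lib), int(row.locus_total_reads_lib)
        b, n2 = int(row.variant_reads_tp), int(row.locus_total_reads_tp)
        change = space.change_for((row.pos, row.ref, row.alt))
        fc = fold_change_from_counts(b, n2, a, n1, policy=policy)
        p = enrichment_test((a, n1), (b, n2), method=test_method)
        p_values.append(p)
        records.append(
            EnrichmentRecord(
                position=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                codon_index=change.codon_index,
                ref_aa=change.ref_aa,
                alt_aa=change.alt_aa,
                effect=change.effect,
                freq_library=variant_frequency(a, n1),
                freq_timepoint=variant_frequency(b, n2),
                fold_change=fc if fc is not None else float("nan"),
                p_value=p,
                q_value=1.0,
                hit=False,
                lib_reads=a,
                tp_reads=b,
            )
        )

    q_values = adjust_bh(p_values)
    for r, q in zip(records, q_values):
        r.q_value = float(q)
    records, n_hits, n_passengers = call_hits(records, params)

    aa_assessed = {
        (r.codon_index, r.alt_aa)
        for r in records
        if r.effect in ("missense", "nonsense")
    }
    coverage = (
        coverage_percent(len(aa_assessed), space.n_aa_coding)
        if space.n_aa_coding
        else 0.0
    )
    return ScreenResult(
        records=records,
        n_assessable=len(records),
        n_hits=n_hits,
        n_passengers=n_passengers,
        coverage_aa_percent=coverage,
        params=params,
        rejects=rejects,
    )


@dataclass
class OverlapReport:
    """Shared members of two screens' top-n fold-change lists."""

    top_n: int
    shared: list[tuple[str, int, int]]  # (aa change, rank in a, rank in b)

    @property
    def n_shared(self) -> int:
        return len(self.shared)


def _top_ranks(result: ScreenResult, top_n: int) -> dict[str, int]:
    ordered = sorted(
        result.records, key=lambda r: (-r.fold_change, r.position, r.alt)
    )
    return {r.aa_change: i + 1 for i, r in enumerate(ordered[:top_n])}


def compare_screens(
    result_a: ScreenResult, result_b: ScreenResult, top_n: int = 10
) -> OverlapReport:
    """Intersection of the two screens' top-n lists by amino acid identity."""
    if not result_a.records or not result_b.records:
        raise ValidationError("both screen results must be non-empty")
    cap = min(top_n, len(result_a.records), len(result_b.records))
    if cap < top_n:
        warnings.warn(f"top_n={top_n} larger than a result; capped at {cap}")
    ranks_a = _top_ranks(result_a, cap)
    ranks_b = _top_ranks(result_b, cap)
    shared = sorted(
        (aa, ranks_a[aa], ranks_b[aa]) for aa in ranks_a.keys() & ranks_b.keys()
    )
    return OverlapReport(top_n=cap, shared=shared)


@dataclass
class ScreenReport:
    """Scatter-plot data, coverage, and spectrum for a scored screen."""

    plot_table: pd.DataFrame  # residue, fold_change, freq_timepoint, hit
    coverage_aa_percent: float
    spectrum: pd.DataFrame

    def plot(self, path: str | Path | None = None):  # pragma: no cover - thin layer
        """Residue-position versus fold-change scatter (dot size = frequency)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        t = self.plot_table
        fig, ax = plt.subplots(figsize=(8, 4))
        if len(t):
            sizes = 10 + 2000 * t["freq_timepoint"]
            ax.scatter(
                t["residue"], t["fold_change"], s=sizes,
                c=np.where(t["hit"], "crimson", "grey"), alpha=0.6, lw=0,
            )
        ax.set_xlabel("residue position")
        ax.set_ylabel("fold change")
        ax.set_yscale("symlog")
        if path is not None:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
        return fig


def screen_report(records: Iterable[EnrichmentRecord], space: VariantSpace) -> ScreenReport:
    """Assemble the report bundle for a scored record set."""
    records = list(records)
    plot_table = pd.DataFrame(
        [
            {
                "residue": r.codon_index,
                "fold_change": r.fold_change,
                "freq_timepoint": r.freq_timepoint,
                "hit": r.hit,
            }
            for r in records
        ],
        columns=["residue", "fold_change", "freq_timepoint", "hit"],
    )
    aa_assessed = {
        (r.codon_index, r.alt_aa)
        for r in records
        if r.effect in ("missense", "nonsense")
    }
    coverage = (
        coverage_percent(len(aa_assessed), space.n_aa_coding)
        if space.n_aa_coding
        else 0.0
    )
    spectrum = spectrum_table_from_records(records)
    return ScreenReport(
        plot_table=plot_table,
        coverage_aa_percent=coverage,
        spectrum=spectrum,
    )


def spectrum_table_from_records(records: Iterable[EnrichmentRecord]) -> pd.DataFrame:
    """Ordered-substitution spectrum of a record collection."""
    from collections import Counter

    from .variant_space import BASES, classify_substitution

    counts: Counter = Counter()
    for r in BASES:
        for a in BASES:
            if r != a:
                counts[(r, a)] = 0
    for rec in records:
        counts[(rec.ref, rec.alt)] += 1
    rows = [
        {
            "ref": r,
            "alt": a,
            "count": counts[(r, a)],
            "subst_class": classify_substitution(r, a),
        }
        for r in BASES
        for a in BASES
        if r != a
    ]
    return pd.DataFrame(rows)
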