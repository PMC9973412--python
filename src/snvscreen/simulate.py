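"""Synthetic screens with known ground truth.

A screen is simulated in three stages, mirroring the physical experiment:

1. random mutagenesis of inserts (Poisson load per insert, configurable
   substitution spectrum),
2. clonal selection under per-variant fitness effects with periodic
   passaging (deterministic exponential growth, or stochastic thinning),
3. deep sequencing emulated as per-locus multinomial sampling of reads.

Clones are tracked at the insert level: a variant's frequency emerges by
marginalizing over every insert that carries it, which reproduces the in-cis
passenger confound of real libraries.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .counts_io import VariantCountTable
from .errors import ValidationError
from .variant_space import (
    BASES,
    AminoAcidChange,
    CodingSequence,
    NucleotideVariant,
    STOP_CODONS,
    VariantSpace,
    aa_change_for,
    enumerate_snv_space,
    make_variant,
)

__all__ = [
    "MutagenesisModel",
    "MutantInsert",
    "FitnessModel",
    "PassageSchedule",
    "SequencingModel",
    "ScreenSimulation",
    "simulate_library",
    "simulate_selection",
    "simulate_counts",
    "simulate_screen",
    "ground_truth",
    "random_cds",
    "pick_missense_effects",
    "scenario_from_dict",
]


@dataclass(frozen=True)
class MutagenesisModel:
    """Error-prone PCR model: Poisson mutation load and substitution spectrum.

    ``spectrum_weights`` maps ordered substitutions (ref, alt) to non-negative
    weights; None means a uniform spectrum.  Weights are normalized per
    reference base when drawing the alternate.
    """

    mean_mutations_per_insert: float
    spectrum_weights: Mapping[tuple[str, str], float] | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.mean_mutations_per_insert < 0:
            raise ValidationError(
                f"mean mutations per insert must be >= 0, got "
                f"{self.mean_mutations_per_insert}"
            )
        if self.spectrum_weights is not None:
            for (r, a), w in self.spectrum_weights.items():
                if w < 0:
                    raise ValidationError(f"negative spectrum weight for {r}->{a}")

    def alt_distribution(self, ref_base: str) -> tuple[tuple[str, ...], np.ndarray]:
        """Alternate bases and their normalized probabilities given a ref base."""
        alts = tuple(b for b in BASES if b != ref_base)
        if self.spectrum_weights is None:
            return alts, np.full(3, 1.0 / 3.0)
        w = np.array([self.spectrum_weights.get((ref_base, a), 0.0) for a in alts])
        total = w.sum()
        if total <= 0:
            return alts, np.full(3, 1.0 / 3.0)
        return alts, w / total


@dataclass(frozen=True)
class MutantInsert:
    """One mutagenized insert: a set of in-cis variants and their aa changes."""

    insert_id: str
    variants: tuple[NucleotideVariant, ...]
    aa_changes: tuple[AminoAcidChange, ...]

    def __post_init__(self):
        positions = [v.position for v in self.variants]
        if len(set(positions)) != len(positions):
            raise ValidationError(
                f"insert {self.insert_id}: multiple variants at one position"
            )


@dataclass
class FitnessModel:
    """Per-clone net growth rates derived from per-variant fitness effects.

    ``effects`` maps (codon_index, alt_aa) to an additive growth-rate
    modifier (per day); unlisted changes are passengers (effect 0).  Multiple
    effects on one insert combine by ``max`` (default: a single activating
    change suffices) or ``sum``.  ``nonsense_penalty`` is subtracted once if
    the insert carries any nonsense change.
    """

    baseline_rate: float = 0.0
    effects: Mapping[tuple[int, str], float] = field(default_factory=dict)
    combine: str = "max"
    nonsense_penalty: float = 0.0

    def __post_init__(self):
        if self.combine not in ("max", "sum"):
            raise ValidationError(f"combine must be 'max' or 'sum', got {self.combine!r}")
        if not math.isfinite(self.baseline_rate):
            raise ValidationError("baseline rate must be finite")

    def clone_rate(self, insert: MutantInsert) -> float:
        deltas = [
            self.effects.get((c.codon_index, c.alt_aa), 0.0)
            for c in insert.aa_changes
        ]
        if not deltas:
            combined = 0.0
        elif self.combine == "max":
            combined = max(max(deltas), 0.0)
        else:
            combined = sum(deltas)
        rate = self.baseline_rate + combined
        if self.nonsense_penalty and any(c.effect == "nonsense" for c in insert.aa_changes):
            rate -= self.nonsense_penalty
        if not math.isfinite(rate):
            raise ValidationError(f"non-finite growth rate for insert {insert.insert_id}")
        return rate


@dataclass(frozen=True)
class PassageSchedule:
    """Culture duration, passaging trigger, and count-sampling days."""

    duration_days: int = 8
    passage_trigger: float = 1e7
    dilution_factor: float = 0.1
    sampling_days: tuple[int, ...] = (8,)

    def __post_init__(self):
        if self.duration_days <= 0:
            raise ValidationError("duration must be positive")
        if not 0 < self.dilution_factor <= 1:
            raise ValidationError(
                f"dilution factor must be in (0, 1], got {self.dilution_factor}"
            )
        for d in self.sampling_days:
            if not 0 <= d <= self.duration_days:
                raise ValidationError(
                    f"sampling day {d} outside culture duration {self.duration_days}"
                )


@dataclass(frozen=True)
class SequencingModel:
    """Per-locus read depth and a uniform base-flip error rate."""

    depth: int = 100_000
    error_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.depth < 1:
            raise ValidationError(f"depth must be >= 1, got {self.depth}")
        if not 0 <= self.error_rate < 0.01:
            raise ValidationError(
                f"error rate must be in [0, 0.01), got {self.error_rate}"
            )


def simulate_library(
    cds: CodingSequence,
    model: MutagenesisModel,
    n_inserts: int,
    rng: np.random.Generator | None = None,
) -> tuple[MutantInsert, ...]:
    """Draw a mutagenized insert pool.

    Per-insert mutation counts are Poisson(mean); positions are uniform over
    the full CDS (stop codon included); alternate bases follow the spectrum
    conditioned on the reference base.  Deterministic under a fixed seed.
    """
    if n_inserts < 1:
        raise ValidationError(f"n_inserts must be >= 1, got {n_inserts}")
    if rng is None:
        rng = np.random.default_rng(model.seed)

    length = cds.length
    counts = rng.poisson(model.mean_mutations_per_insert, size=n_inserts)
    inserts = []
    for i, k in enumerate(counts):
        k = min(int(k), length)
        variants: list[NucleotideVariant] = []
        if k:
            positions = rng.choice(length, size=k, replace=False) + 1
            for pos in sorted(int(p) for p in positions):
                ref = cds.sequence[pos - 1]
                alts, probs = model.alt_distribution(ref)
                alt = alts[rng.choice(3, p=probs)]
                variants.append(make_variant(cds, pos, alt))
        inserts.append(
            MutantInsert(
                insert_id=f"ins{i:06d}",
                variants=tuple(variants),
                aa_changes=tuple(aa_change_for(v) for v in variants),
            )
        )
    return tuple(inserts)


def simulate_selection(
    inserts: Sequence[MutantInsert],
    fitness: FitnessModel,
    schedule: PassageSchedule,
    mode: str = "deterministic",
    seed: int | None = None,
    initial_abundance: float = 100.0,
) -> dict[int, np.ndarray]:
    """Clone abundance trajectories under exponential growth with passaging.

    Deterministic mode: ``a_i(t) = a_i(0) * exp(r_i * t)`` with all clones
    rescaled by the dilution factor whenever the pool exceeds the trigger —
    relative frequencies are invariant to these global dilutions.  Stochastic
    mode implements each passage as per-clone binomial thinning.

    Returns a map from sampling day (plus day 0) to the abundance vector.
    """
    if mode not in ("deterministic", "stochastic"):
        raise ValidationError(f"mode must be deterministic|stochastic, got {mode!r}")
    if not schedule.sampling_days:
        raise ValidationError("schedule has no sampling days")
    rng = np.random.default_rng(seed)

    rates = np.array([fitness.clone_rate(ins) for ins in inserts], dtype=float)
    growth = np.exp(rates)  # per-day factors
    a = np.full(len(inserts), float(initial_abundance))
    wanted = set(schedule.sampling_days)
    out: dict[int, np.ndarray] = {0: a.copy()}

    for day in range(1, schedule.duration_days + 1):
        a = a * growth
        if a.sum() > schedule.passage_trigger:
            if mode == "deterministic":
                a = a * schedule.dilution_factor
            else:
                a = rng.binomial(
                    np.round(a).astype(np.int64), schedule.dilution_factor
                ).astype(float)
        if day in wanted:
            out[day] = a.copy()
    return out


def simulate_counts(
    abundances: np.ndarray,
    inserts: Sequence[MutantInsert],
    cds: CodingSequence,
    seqmodel: SequencingModel,
    sample_id: str = "sample",
    rng: np.random.Generator | None = None,
) -> VariantCountTable:
    """Sample per-locus read counts from clone frequencies.

    At each CDS locus, ``depth`` reads are drawn multinomially: a clone
    contributes its alternate base at mutated loci and the reference
    elsewhere.  Sequencing errors flip a read to a uniformly chosen alternate
    at ``error_rate``.  Per-locus totals always equal the depth.
    """
    abundances = np.asarray(abundances, dtype=float)
    if len(abundances) != len(inserts):
        raise ValidationError("abundance vector does not match insert count")
    if np.any(abundances < 0):
        raise ValidationError("abundances must be non-negative")
    total = abundances.sum()
    if total <= 0:
        raise ValidationError("total abundance is zero")
    if rng is None:
        rng = np.random.default_rng(seqmodel.seed)

    freqs = abundances / total
    alt_freq: dict[int, dict[str, float]] = defaultdict(lambda: defaultdict(float))
    for f, ins in zip(freqs, inserts):
        if f == 0:
            continue
        for v in ins.variants:
            alt_freq[v.position][v.alt_base] += f

    e = seqmodel.error_rate
    depth = seqmodel.depth
    base_index = {b: i for i, b in enumerate(BASES)}
    rows = []
    for pos in range(1, cds.length + 1):
        locus = alt_freq.get(pos)
        if locus is None and e == 0:
            continue  # all reads are reference; no variant rows
        ref = cds.sequence[pos - 1]
        p = np.zeros(4)
        if locus:
            for alt, f in locus.items():
                p[base_index[alt]] = f
        p[base_index[ref]] = 1.0 - p.sum()
        if e > 0:
            p = p * (1.0 - e) + (1.0 - p) * (e / 3.0)
        counts = rng.multinomial(depth, p / p.sum())
        for b, n in zip(BASES, counts):
            if b != ref and n > 0:
                rows.append((pos, ref, b, int(n), depth))

    frame = pd.DataFrame(
        rows, columns=["pos", "ref", "alt", "variant_reads", "locus_total_reads"]
    )
    return VariantCountTable(sample_id, frame)


@dataclass
class ScreenSimulation:
    """Bundle of a simulated screen: inputs, trajectories, counts, truth."""

    cds: CodingSequence
    space: VariantSpace
    inserts: tuple[MutantInsert, ...]
    fitness: FitnessModel
    schedule: PassageSchedule
    seqmodel: SequencingModel
    trajectories: dict[int, np.ndarray]
    library_counts: VariantCountTable
    timepoint_counts: dict[int, VariantCountTable]
    seed: int | None = None


def simulate_screen(
    cds: CodingSequence,
    mutagenesis: MutagenesisModel,
    fitness: FitnessModel,
    schedule: PassageSchedule,
    seqmodel: SequencingModel,
    n_inserts: int,
    mode: str = "deterministic",
    seed: int | None = None,
) -> ScreenSimulation:
    """Run library generation, selection, and count sampling end to end.

    A single ``seed`` drives every stage; identical seeds give bit-identical
    simulations.
    """
    rng = np.random.default_rng(seed)
    inserts = simulate_library(cds, mutagenesis, n_inserts, rng=rng)
    traj = simulate_selection(
        inserts, fitness, schedule, mode=mode,
        seed=int(rng.integers(2**31)),
    )
    library_counts = simulate_counts(
        np.ones(len(inserts)), inserts, cds, seqmodel, sample_id="library", rng=rng
    )
    timepoints = {
        day: simulate_counts(
            traj[day], inserts, cds, seqmodel, sample_id=f"day{day}", rng=rng
        )
        for day in schedule.sampling_days
    }
    return ScreenSimulation(
        cds=cds,
        space=enumerate_snv_space(cds),
        inserts=inserts,
        fitness=fitness,
        schedule=schedule,
        seqmodel=seqmodel,
        trajectories=traj,
        library_counts=library_counts,
        timepoint_counts=timepoints,
        seed=seed,
    )


def ground_truth(sim: ScreenSimulation) -> pd.DataFrame:
    """The planted activating changes and their growth-rate effects."""
    rows = [
        {"codon_index": ci, "alt_aa": aa, "delta_rate": dr}
        for (ci, aa), dr in sorted(sim.fitness.effects.items())
        if dr > 0
    ]
    return pd.DataFrame(rows, columns=["codon_index", "alt_aa", "delta_rate"])


def random_cds(
    n_codons: int, seed: int | None = None, cds_id: str = "synthetic_cds"
) -> CodingSequence:
    """A random in-frame CDS: ATG start, no internal stops, TAA-family stop."""
    if n_codons < 3:
        raise ValidationError("need at least 3 codons (start, one internal, stop)")
    rng = np.random.default_rng(seed)
    sense = _non_stop_codons()
    codons = ["ATG"]
    idx = rng.integers(0, len(sense), size=n_codons - 2)
    codons.extend(sense[i] for i in idx)
    codons.append(("TAA", "TAG", "TGA")[rng.integers(0, 3)])
    return CodingSequence(id=cds_id, sequence="".join(codons), includes_stop=True)


def _non_stop_codons() -> list[str]:
    return sorted(
        "".join(c)
        for c in itertools.product("ACGT", repeat=3)
        if "".join(c) not in STOP_CODONS
    )


def pick_missense_effects(
    space: VariantSpace,
    n_effects: int,
    delta_min: float,
    delta_max: float,
    seed: int | None = None,
) -> dict[tuple[int, str], float]:
    """Plant activating missense effects at distinct codons.

    Effect sizes are spaced evenly across ``[delta_min, delta_max]`` so that
    the induced fold-change rank order is known exactly.
    """
    rng = np.random.default_rng(seed)
    by_codon: dict[int, list[tuple[int, str]]] = defaultdict(list)
    for key, effect in space.aa_changes.items():
        if effect == "missense" and key[0] > 1:  # avoid the start codon
            by_codon[key[0]].append(key)
    codons = sorted(by_codon)
    if len(codons) < n_effects:
        raise ValidationError(
            f"space has only {len(codons)} missense-capable codons, need {n_effects}"
        )
    chosen_codons = rng.choice(len(codons), size=n_effects, replace=False)
    deltas = (
        np.linspace(delta_min, delta_max, n_effects)
        if n_effects > 1
        else np.array([(delta_min + delta_max) / 2.0])
    )
    effects = {}
    for ci_idx, dr in zip(sorted(int(c) for c in chosen_codons), deltas):
        options = sorted(by_codon[codons[ci_idx]])
        key = options[rng.integers(0, len(options))]
        effects[key] = float(dr)
    return effects


def scenario_from_dict(cfg: dict, seed: int | None = None) -> ScreenSimulation:
    """Build and run a screen from a plain configuration mapping.

    Expected keys (all optional except one of cds/cds_fasta):
    ``cds_fasta`` | ``cds: {n_codons}``, ``n_inserts``, ``mutagenesis:
    {mean}``, ``fitness: {baseline_rate, n_activating, delta_min, delta_max}``
    or ``fitness: {effects: [{codon_index, alt_aa, delta}]}``, ``schedule``,
    ``sequencing: {depth, error_rate}``, ``mode``.
    """
    rng = np.random.default_rng(seed)
    if "cds_fasta" in cfg:
        cds = CodingSequence.from_fasta(cfg["cds_fasta"])
    else:
        n_codons = int(cfg.get("cds", {}).get("n_codons", 900))
        cds = random_cds(n_codons, seed=int(rng.integers(2**31)))

    mut_cfg = cfg.get("mutagenesis", {})
    mutagenesis = MutagenesisModel(
        mean_mutations_per_insert=float(mut_cfg.get("mean", 2.59))
    )

    fit_cfg = cfg.get("fitness", {})
    if "effects" in fit_cfg:
        effects = {
            (int(e["codon_index"]), str(e["alt_aa"])): float(e["delta"])
            for e in fit_cfg["effects"]
        }
    else:
        n_act = int(fit_cfg.get("n_activating", 10))
        if n_act > 0:
            space = enumerate_snv_space(cds)
            effects = pick_missense_effects(
                space,
                n_act,
                float(fit_cfg.get("delta_min", 0.75)),
                float(fit_cfg.get("delta_max", 1.0)),
                seed=int(rng.integers(2**31)),
            )
        else:
            effects = {}
    fitness = FitnessModel(
        baseline_rate=float(fit_cfg.get("baseline_rate", 0.3)),
        effects=effects,
        combine=str(fit_cfg.get("combine", "max")),
    )

    sch_cfg = cfg.get("schedule", {})
    schedule = PassageSchedule(
        duration_days=int(sch_cfg.get("duration_days", 8)),
        passage_trigger=float(sch_cfg.get("passage_trigger", 1e7)),
        dilution_factor=float(sch_cfg.get("dilution_factor", 0.1)),
        sampling_days=tuple(int(d) for d in sch_cfg.get("sampling_days", [8])),
    )

    seq_cfg = cfg.get("sequencing", {})
    seqmodel = SequencingModel(
        depth=int(seq_cfg.get("depth", 100_000)),
        error_rate=float(seq_cfg.get("error_rate", 0.0)),
    )

    return simulate_screen(
        cds,
        mutagenesis,
        fitness,
        schedule,
        seqmodel,
        n_inserts=int(cfg.get("n_inserts", 60_000)),
        mode=str(cfg.get("mode", "deterministic")),
        seed=int(rng.integers(2**31)),
    )
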