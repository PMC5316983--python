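"""Synthetic data: library enrichment, patient profiling and FASTQ emission.

This module generates every input the pipeline consumes, with known ground
truth so that downstream statistics can be tested against what was planted.

Three layers are simulated:

1. **Library enrichment** — a naive pool of unique 35-mers is subjected to
   iterated positive selection / counter-selection / positive selection with
   PCR amplification in between, run in two arms (a disease cohort and a
   control cohort) whose products are mixed into a common profiling library.
   Capture is modelled as Poisson thinning with per-molecule capture weight
   ``background + affinity(seq, target) * abundance(target)`` — linear in
   target abundance with an additive non-specific floor, the simplest
   mechanism that yields cohort-specific enrichment and diversity collapse.
2. **Patient profiling** — a library is incubated against a patient whose
   personal target abundances are the cohort's plasma profile perturbed by
   log-normal biological noise; recovered counts are multinomial at a fixed
   sequencing depth, with gamma overdispersion between technical replicates.
3. **Read emission** — per-sample counts are written as staggered amplicon
   FASTQ reads with a configurable substitution error rate.

All randomness flows from explicit integer seeds; identical configurations
reproduce identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DNA_ALPHABET, LibraryDesign

__all__ = [
    "EnrichmentState",
    "PlasmaModel",
    "AffinityModel",
    "PatientProfile",
    "EnrichmentConfig",
    "EnrichmentRun",
    "make_naive_library",
    "selection_round",
    "pcr_amplify",
    "aliquot",
    "mix_states",
    "run_enrichment",
    "select_l2000",
    "make_patient",
    "simulate_patient_counts",
    "default_profiling_system",
    "simulate_cohort_matrix",
    "write_fastq",
]

_MAX_UNIQUE = 4 ** 35


def random_sequences(n: int, length: int, rng: np.random.Generator) -> np.ndarray:
    """n distinct random DNA strings of the given length."""
    letters = np.frombuffer("".join(DNA_ALPHABET).encode(), dtype="S1")
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        draw = letters[rng.integers(0, 4, size=(n - len(out), length))]
        for row in draw.view(f"S{length}").ravel():
            s = row.decode()
            if s not in seen:
                seen.add(s)
                out.append(s)
    return np.array(out, dtype=object)


@dataclass
class EnrichmentState:
    """A library population: which sequences exist and at what copy number.

    ``universe`` is the full sequence catalogue created with the naive
    library; ``ids`` index into it and ``copies`` are real-valued copy
    numbers (fractional after noisy PCR).  Selection can only remove
    sequences, so the unique count never increases within a branch.
    """

    universe: np.ndarray
    ids: np.ndarray
    copies: np.ndarray
    branch: str = "L0"
    round: int = 0
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.copies):
            raise ValueError("ids and copies must align")
        if len(self.copies) and float(np.min(self.copies)) < 0:
            raise ValueError("copy numbers must be >= 0")

    @property
    def sequences(self) -> np.ndarray:
        return self.universe[self.ids]

    @property
    def unique_count(self) -> int:
        return int(np.sum(self.copies > 0))

    @property
    def total_copies(self) -> float:
        return float(self.copies.sum())

    @property
    def mean_copies(self) -> float:
        n = self.unique_count
        return self.total_copies / n if n else 0.0

    @property
    def population(self) -> dict[str, float]:
        return dict(zip(self.sequences, self.copies))

    def shares(self) -> np.ndarray:
        total = self.total_copies
        return self.copies / total if total > 0 else self.copies

    def compact(self) -> "EnrichmentState":
        keep = self.copies > 0
        return replace(self, ids=self.ids[keep], copies=self.copies[keep])


@dataclass
class PlasmaModel:
    """Target abundances presented by one cohort's pooled plasma."""

    cohort: str
    target_abundances: np.ndarray
    shared_mask: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.target_abundances)):
            raise ValueError("target abundances must be finite")
        if np.any(self.target_abundances < 0):
            raise ValueError("target abundances must be >= 0")


@dataclass
class AffinityModel:
    """Sequence -> target affinities plus a non-specific background rate.

    Each sequence binds at most one target (``target_of`` is -1 for
    non-binders).  ``background`` > 0 so no molecule has capture
    probability exactly zero.
    """

    target_of: np.ndarray
    affinity: np.ndarray
    background: float

    def __post_init__(self) -> None:
        if self.background <= 0:
            raise ValueError("background capture rate must be > 0")
        if np.any(self.affinity < 0):
            raise ValueError("affinities must be >= 0")

    def weights(self, ids: np.ndarray, abundances: np.ndarray) -> np.ndarray:
        """Per-molecule capture weight: background + affinity * abundance."""
        t = self.target_of[ids]
        specific = np.where(
            t >= 0, self.affinity[ids] * abundances[np.maximum(t, 0)], 0.0
        )
        return self.background + specific


@dataclass
class PatientProfile:
    """One patient's personal target abundances and replicate noise."""

    patient_id: str
    cohort: str
    target_abundance: np.ndarray
    replicate_overdispersion: float = 0.02

    def __post_init__(self) -> None:
        if np.any(self.target_abundance < 0):
            raise ValueError("patient abundances must be >= 0")


def make_naive_library(
    n_unique: int,
    abundance_sd_log: float = 0.3,
    seed: int = 0,
    mean_copies: float = 3.0,
) -> EnrichmentState:
    """A naive pool: ``n_unique`` random 35-mers at low, mildly dispersed
    copy numbers (log-normal, mean ``mean_copies``).  Deterministic by seed."""
    if n_unique < 1:
        raise ValueError("n_unique must be >= 1")
    if n_unique > _MAX_UNIQUE:
        raise ValueError("n_unique exceeds the 35-mer sequence space")
    rng = np.random.default_rng(seed)
    universe = random_sequences(n_unique, 35, rng)
    if abundance_sd_log > 0:
        mu = np.log(mean_copies) - abundance_sd_log**2 / 2
        copies = rng.lognormal(mean=mu, sigma=abundance_sd_log, size=n_unique)
    else:
        copies = np.full(n_unique, float(mean_copies))
    return EnrichmentState(
        universe=universe,
        ids=np.arange(n_unique),
        copies=copies,
        branch="L0",
        round=0,
        history=[f"make_naive_library(n={n_unique}, sdlog={abundance_sd_log}, seed={seed})"],
    )


def selection_round(
    state: EnrichmentState,
    plasma: PlasmaModel,
    aff: AffinityModel,
    mode: str,
    capture_depth: int,
    seed: int = 0,
) -> EnrichmentState:
    """One partitioning step against a plasma sample.

    Capture probability per molecule is proportional to
    ``background + affinity * abundance``, scaled so the expected number of
    captured molecules is ``capture_depth``; molecule-level sampling is
    approximated by Poisson thinning.  ``positive`` returns the captured
    fraction (pellet); ``counter`` returns the remainder (supernatant).
    """
    if mode not in ("positive", "counter"):
        raise ValueError(f"mode must be 'positive' or 'counter', got {mode!r}")
    if capture_depth < 1:
        raise ValueError("capture_depth must be >= 1")
    if state.unique_count == 0:
        raise ValueError("selection on an empty population")
    rng = np.random.default_rng(seed)
    w = aff.weights(state.ids, plasma.target_abundances)
    mass = float(np.sum(state.copies * w))
    p = np.minimum(1.0, capture_depth * w / mass)
    captured = np.minimum(rng.poisson(state.copies * p), np.ceil(state.copies))
    if mode == "positive":
        new_copies = captured.astype(float)
    else:
        new_copies = np.maximum(state.copies - captured, 0.0)
    out = replace(
        state,
        copies=new_copies,
        history=state.history
        + [f"selection_round({mode}, plasma={plasma.cohort}, depth={capture_depth}, seed={seed})"],
    )
    return out.compact()


def pcr_amplify(
    state: EnrichmentState,
    cycles: int,
    efficiency: float,
    seed: int = 0,
    noise_sdlog: float = 0.0,
) -> EnrichmentState:
    """Multiply each copy number by a draw centred on (1+efficiency)^cycles.

    The unique-sequence set is unchanged; with ``noise_sdlog`` 0 the
    multiplication is exact.
    """
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    if not (0 < efficiency <= 1):
        raise ValueError("efficiency must lie in (0, 1]")
    if cycles == 0:
        return state
    factor = (1.0 + efficiency) ** cycles
    copies = state.copies * factor
    if noise_sdlog > 0:
        rng = np.random.default_rng(seed)
        copies = copies * rng.lognormal(
            mean=-noise_sdlog**2 / 2, sigma=noise_sdlog, size=len(copies)
        )
    return replace(
        state,
        copies=copies,
        history=state.history
        + [f"pcr_amplify(cycles={cycles}, eff={efficiency}, seed={seed})"],
    )


def aliquot(state: EnrichmentState, total: float, seed: int = 0) -> EnrichmentState:
    """Subsample the pool down to ~``total`` molecules (Poisson thinning).

    Mirrors taking a fixed-size aliquot of a PCR product into the next
    selection round; low-copy sequences can drop out here.
    """
    current = state.total_copies
    if current <= 0:
        raise ValueError("aliquot of an empty population")
    f = total / current
    if f >= 1:
        return state
    rng = np.random.default_rng(seed)
    copies = rng.poisson(state.copies * f).astype(float)
    out = replace(
        state,
        copies=copies,
        history=state.history + [f"aliquot(total={total:g}, seed={seed})"],
    )
    return out.compact()


def mix_states(a: EnrichmentState, b: EnrichmentState, branch: str = "L3") -> EnrichmentState:
    """Mix two branches at equal total copy mass."""
    if a.universe is not b.universe:
        raise ValueError("can only mix states over the same sequence universe")
    target = (a.total_copies + b.total_copies) / 2
    n = len(a.universe)
    copies = np.zeros(n)
    np.add.at(copies, a.ids, a.copies * (target / a.total_copies))
    np.add.at(copies, b.ids, b.copies * (target / b.total_copies))
    keep = copies > 0
    return EnrichmentState(
        universe=a.universe,
        ids=np.nonzero(keep)[0],
        copies=copies[keep],
        branch=branch,
        round=max(a.round, b.round),
        history=[f"mix({a.branch}, {b.branch})"],
    )


@dataclass
class EnrichmentConfig:
    """Study conditions for the enrichment simulation.

    The default naive pool of 1e5 unique sequences is a desk-scale stand-in
    for the experimental 1e11 -> 1e6 regime and preserves the
    diversity-collapse dynamics.  1% of sequences are planted binders,
    split between disease-specific, control-specific and shared targets.
    """

    n_unique: int = 100_000
    naive_sdlog: float = 0.3
    naive_mean_copies: float = 3.0
    n_targets: int = 200
    frac_specific_targets: float = 0.3    # per cohort; remainder shared
    target_sdlog: float = 0.5
    frac_binders: float = 0.01
    affinity_mean: float = 50.0
    affinity_sdlog: float = 0.3
    background: float = 1.0
    capture_fraction: float = 0.25        # positive rounds
    counter_capture_fraction: float = 0.25
    pcr_cycles: int = 10
    pcr_efficiency: float = 0.6
    pcr_noise_sdlog: float = 0.05
    iterations: int = 3
    seed: int = 0


@dataclass
class EnrichmentRun:
    """Outcome of a full multi-iteration enrichment."""

    l1: EnrichmentState
    l2: EnrichmentState
    l3: EnrichmentState
    per_iteration: pd.DataFrame          # unique count / mean copies of L3 per iteration
    plasma_cancer: PlasmaModel
    plasma_control: PlasmaModel
    affinity: AffinityModel
    ground_truth: dict


def _build_system(cfg: EnrichmentConfig, rng: np.random.Generator):
    n_t = cfg.n_targets
    n_spec = int(round(cfg.frac_specific_targets * n_t))
    cancer_targets = np.arange(0, n_spec)
    control_targets = np.arange(n_spec, 2 * n_spec)
    shared = np.ones(n_t, dtype=bool)
    shared[: 2 * n_spec] = False

    base = rng.lognormal(mean=0.0, sigma=cfg.target_sdlog, size=n_t)
    abund_c = base.copy()
    abund_n = base.copy()
    abund_c[control_targets] *= 1e-3    # control-specific targets absent in cancer plasma
    abund_n[cancer_targets] *= 1e-3
    plasma_c = PlasmaModel("cancer", abund_c, shared)
    plasma_n = PlasmaModel("non_cancer", abund_n, shared)

    n_binders = max(1, int(round(cfg.frac_binders * cfg.n_unique)))
    binder_ids = rng.choice(cfg.n_unique, size=n_binders, replace=False)
    target_of = np.full(cfg.n_unique, -1, dtype=np.int64)
    # 40% of binders to disease-specific, 40% control-specific, 20% shared
    n_c = int(round(0.4 * n_binders))
    n_n = int(round(0.4 * n_binders))
    groups = [
        (binder_ids[:n_c], cancer_targets),
        (binder_ids[n_c : n_c + n_n], control_targets),
        (binder_ids[n_c + n_n :], np.nonzero(shared)[0]),
    ]
    for ids_, pool in groups:
        if len(ids_) and len(pool):
            target_of[ids_] = rng.choice(pool, size=len(ids_))
    affinity = np.zeros(cfg.n_unique)
    affinity[binder_ids] = rng.lognormal(
        mean=np.log(cfg.affinity_mean) - cfg.affinity_sdlog**2 / 2,
        sigma=cfg.affinity_sdlog,
        size=n_binders,
    )
    aff = AffinityModel(target_of=target_of, affinity=affinity, background=cfg.background)
    truth = {
        "cancer_binders": np.sort(binder_ids[:n_c]),
        "control_binders": np.sort(binder_ids[n_c : n_c + n_n]),
        "shared_binders": np.sort(binder_ids[n_c + n_n :]),
    }
    return plasma_c, plasma_n, aff, truth


def _enrich_arm(
    state: EnrichmentState,
    own: PlasmaModel,
    other: PlasmaModel,
    aff: AffinityModel,
    cfg: EnrichmentConfig,
    seeds: np.ndarray,
    branch: str,
) -> EnrichmentState:
    """positive -> counter -> positive -> PCR on one cohort arm."""
    depth = max(1, int(cfg.capture_fraction * state.total_copies))
    s = selection_round(state, own, aff, "positive", depth, seed=int(seeds[0]))
    depth = max(1, int(cfg.counter_capture_fraction * s.total_copies))
    s = selection_round(s, other, aff, "counter", depth, seed=int(seeds[1]))
    depth = max(1, int(cfg.capture_fraction * s.total_copies))
    s = selection_round(s, own, aff, "positive", depth, seed=int(seeds[2]))
    s = pcr_amplify(
        s, cfg.pcr_cycles, cfg.pcr_efficiency, seed=int(seeds[3]),
        noise_sdlog=cfg.pcr_noise_sdlog,
    )
    return replace(s, branch=branch, round=state.round + 1)


def run_enrichment(cfg: EnrichmentConfig | None = None) -> EnrichmentRun:
    """Iterated two-arm enrichment: each iteration runs positive selection
    on the own cohort, counter-selection on the other, a second positive
    selection and PCR, in both arms; the arm products L1 (disease) and L2
    (control) are mixed at equal mass into L3, which seeds the next
    iteration after taking a fixed-size aliquot."""
    cfg = cfg or EnrichmentConfig()
    master = np.random.SeedSequence(cfg.seed)
    seeds = master.generate_state(9 * cfg.iterations + 4) % (2**31)
    rng = np.random.default_rng(seeds[0])
    plasma_c, plasma_n, aff, truth = _build_system(cfg, rng)

    state = make_naive_library(
        cfg.n_unique, cfg.naive_sdlog, seed=int(seeds[1]), mean_copies=cfg.naive_mean_copies
    )
    aliquot_total = cfg.n_unique * cfg.naive_mean_copies

    l1 = l2 = l3 = state
    rows = []
    k = 2
    for it in range(1, cfg.iterations + 1):
        inp = aliquot(state, aliquot_total, seed=int(seeds[k])) if it > 1 else state
        k += 1
        l1 = _enrich_arm(inp, plasma_c, plasma_n, aff, cfg, seeds[k : k + 4], "L1")
        k += 4
        l2 = _enrich_arm(inp, plasma_n, plasma_c, aff, cfg, seeds[k : k + 4], "L2")
        k += 4
        l3 = mix_states(l1, l2, branch="L3")
        l3 = replace(l3, round=it)
        rows.append(
            {
                "iteration": it,
                "unique": l3.unique_count,
                "mean_copies": l3.mean_copies,
                "unique_l1": l1.unique_count,
                "unique_l2": l2.unique_count,
            }
        )
        state = l3
    return EnrichmentRun(
        l1=l1,
        l2=l2,
        l3=l3,
        per_iteration=pd.DataFrame(rows),
        plasma_cancer=plasma_c,
        plasma_control=plasma_n,
        affinity=aff,
        ground_truth=truth,
    )


def select_l2000(
    stats: pd.DataFrame,
    n: int = 2000,
) -> list[str]:
    """Pick the top-n sequences for an equimolar resynthesized sub-library.

    ``stats`` is indexed by sequence and carries p-value columns (any
    column starting with ``p_``) and a ``fold_change`` column.  Ranking is
    by smallest p across tests, ties broken by fold-change departure from
    1.  The returned library is equimolar by construction (each member is
    synthesized at the same concentration).
    """
    pcols = [c for c in stats.columns if c.startswith("p_")]
    if not pcols:
        raise ValueError("stats must contain p-value columns (p_*)")
    score = stats[pcols].min(axis=1)
    fc = stats["fold_change"] if "fold_change" in stats.columns else pd.Series(1.0, index=stats.index)
    departure = np.maximum(fc, 1.0 / fc.replace(0, np.nan)).fillna(np.inf)
    order = pd.DataFrame({"p": score, "dep": -departure}).sort_values(["p", "dep"]).index
    if len(order) < n:
        warnings.warn(
            f"only {len(order)} candidates available for a {n}-member library",
            stacklevel=2,
        )
        return list(order)
    return list(order[:n])


def equimolar_state(sequences: Sequence[str], branch: str = "L2000") -> EnrichmentState:
    """An equimolar library over the given sequences."""
    universe = np.array(list(sequences), dtype=object)
    return EnrichmentState(
        universe=universe,
        ids=np.arange(len(universe)),
        copies=np.ones(len(universe)),
        branch=branch,
        history=[f"equimolar({len(universe)})"],
    )


def make_patient(
    plasma: PlasmaModel,
    patient_id: str,
    bio_sdlog: float = 0.4,
    replicate_overdispersion: float = 0.02,
    seed: int = 0,
) -> PatientProfile:
    """Personal target abundances: cohort plasma x per-target log-normal
    biological noise (sdlog 0.4 by default, placing inter-patient profile
    correlation in the observed 0.7-0.9 band)."""
    rng = np.random.default_rng(seed)
    noise = rng.lognormal(
        mean=-bio_sdlog**2 / 2, sigma=bio_sdlog, size=len(plasma.target_abundances)
    )
    return PatientProfile(
        patient_id=patient_id,
        cohort=plasma.cohort,
        target_abundance=plasma.target_abundances * noise,
        replicate_overdispersion=replicate_overdispersion,
    )


def simulate_patient_counts(
    library: EnrichmentState,
    patient: PatientProfile,
    aff: AffinityModel,
    depth: int = 1_000_000,
    seed: int = 0,
    n_replicates: int = 1,
) -> np.ndarray:
    """Recovered-read counts for one patient, shape (n_sequences, n_replicates).

    Expected recovery per sequence is library abundance x (background +
    affinity x patient target abundance); each replicate draws the
    sequence's expectation through a small gamma overdispersion and then a
    multinomial at exactly ``depth`` reads (columns sum to depth).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    w = aff.weights(library.ids, patient.target_abundance)
    expected = library.copies * w
    out = np.zeros((len(expected), n_replicates), dtype=np.int64)
    od = patient.replicate_overdispersion
    for r in range(n_replicates):
        lam = expected
        if od > 0:
            shape = 1.0 / od**2
            lam = expected * rng.gamma(shape, 1.0 / shape, size=len(expected))
        out[:, r] = rng.multinomial(depth, lam / lam.sum())
    return out


def default_profiling_system(
    n_sequences: int = 2000,
    n_targets: int = 500,
    affinity_sdlog: float = 1.0,
    target_sdlog: float = 0.5,
    background_frac: float = 0.05,
    seed: int = 0,
) -> tuple[EnrichmentState, PlasmaModel, AffinityModel]:
    """An equimolar profiling library in which every member is a binder.

    Emulates a resynthesized sub-library: each sequence binds one target
    with log-normal affinity; the background is a small fraction of the
    mean specific signal, so profiles are signal-dominated.
    """
    rng = np.random.default_rng(seed)
    universe = random_sequences(n_sequences, 35, rng)
    lib = EnrichmentState(
        universe=universe,
        ids=np.arange(n_sequences),
        copies=np.ones(n_sequences),
        branch="L2000",
        history=["default_profiling_system"],
    )
    abund = rng.lognormal(mean=0.0, sigma=target_sdlog, size=n_targets)
    plasma = PlasmaModel("pooled", abund, np.ones(n_targets, dtype=bool))
    target_of = rng.integers(0, n_targets, size=n_sequences)
    affinity = rng.lognormal(mean=-affinity_sdlog**2 / 2, sigma=affinity_sdlog, size=n_sequences)
    background = background_frac * float(np.mean(affinity * abund[target_of]))
    aff = AffinityModel(target_of=target_of, affinity=affinity, background=background)
    return lib, plasma, aff


def simulate_cohort_matrix(
    n_features: int = 2000,
    group_sizes: Mapping[str, int] | None = None,
    n_informative: int = 50,
    effect_size: float = 0.5,
    informative_groups: Sequence[str] = ("cancer",),
    base_sdlog: float = 1.0,
    feature_sdlog: float = 1.0,
    scale: float = 100.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Normalized-count-like features x samples matrix with planted signal.

    Each feature is log-normal: log values are N(mu_f, feature_sdlog) with
    feature baselines mu_f ~ N(0, base_sdlog).  The first ``n_informative``
    features get a mean shift of ``effect_size`` standard deviations (on
    the log scale) in the listed groups.  Returns (matrix, labels,
    informative feature indices).
    """
    group_sizes = dict(group_sizes or {"cancer": 100, "control": 100})
    rng = np.random.default_rng(seed)
    labels = []
    sample_ids = []
    for g, n in group_sizes.items():
        labels += [g] * n
        sample_ids += [f"{g}_{i:03d}" for i in range(n)]
    labels = pd.Series(labels, index=sample_ids, name="cohort")
    n_samples = len(labels)

    mu = rng.normal(0.0, base_sdlog, size=n_features)
    log_x = mu[:, None] + rng.normal(0.0, feature_sdlog, size=(n_features, n_samples))
    info_idx = np.arange(min(n_informative, n_features))
    shift_cols = labels.isin(informative_groups).to_numpy()
    log_x[np.ix_(info_idx, np.nonzero(shift_cols)[0])] += effect_size * feature_sdlog
    data = pd.DataFrame(
        scale * np.exp(log_x),
        index=[f"feat_{i:05d}" for i in range(n_features)],
        columns=sample_ids,
    )
    return data, labels, info_idx


def write_fastq(
    table,
    design: LibraryDesign,
    path: str | Path,
    error_rate: float = 0.0,
    seed: int = 0,
    read_length: int | None = None,
) -> int:
    """Emit per-sample counts as staggered single-end amplicon FASTQ.

    Each molecule becomes one read: random stagger pad, variable region,
    constant anchor, the sample's i7 index, then adapter fill, truncated to
    ``read_length``.  Substitutions are applied per base at ``error_rate``
    and qualities are constant and consistent with it.  Returns the number
    of records written.  ``table`` is a :class:`~adaptseq.counts.CountTable`
    or a mapping sample_id -> {sequence: count}.
    """
    if not (0 <= error_rate < 1):
        raise ValueError("error_rate must be in [0, 1)")
    from .counts import CountTable  # local import to avoid a cycle

    if isinstance(table, CountTable):
        sample_counts = {
            s: {seq: int(c) for seq, c in table.data[s].items() if c > 0}
            for s in table.sample_ids
        }
    else:
        sample_counts = {s: dict(m) for s, m in table.items()}

    for sample in sample_counts:
        if sample not in design.i7_indices:
            raise KeyError(f"sample {sample!r} has no i7 index in the design")

    rng = np.random.default_rng(seed)
    letters = DNA_ALPHABET
    offsets = sorted(design.stagger_offsets)
    anchor = design.anchor
    if read_length is None:
        read_length = design.min_read_length() + 8
    q = 40 if error_rate == 0 else min(40, int(round(-10 * np.log10(error_rate))))
    qual_char = chr(q + 33)

    n_written = 0
    path = Path(path)
    with open(path, "wt") as fh:
        for sample, counts in sample_counts.items():
            index = design.i7_indices[sample]
            for seq, count in counts.items():
                if len(seq) != design.variable_length:
                    raise ValueError(
                        f"sequence length {len(seq)} != design variable_length "
                        f"{design.variable_length}"
                    )
                pads = rng.choice(offsets, size=count)
                for i in range(count):
                    pad = "".join(
                        letters[j] for j in rng.integers(0, 4, size=int(pads[i]))
                    )
                    read = (pad + seq + anchor + index + design.p7_adapter)[:read_length]
                    if len(read) < read_length:
                        read = read + "A" * (read_length - len(read))
                    if error_rate > 0:
                        bases = list(read)
                        hits = np.nonzero(rng.random(len(bases)) < error_rate)[0]
                        for h in hits:
                            alternatives = letters.replace(bases[h], "")
                            bases[h] = alternatives[rng.integers(0, 3)]
                        read = "".join(bases)
                    n_written += 1
                    fh.write(
                        f"@{sample}:{n_written}\n{read}\n+\n{qual_char * len(read)}\n"
                    )
    return n_written
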