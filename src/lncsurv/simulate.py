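"""Synthetic cohorts with planted regulons, survival signal, copy-number
events and essentiality scores.

The generator encodes the structure the downstream analysis assumes: latent
per-sample lncRNA activities drive signed, weighted target-gene expression
(plus an independent gene-specific component and noise); microarray-like
cohorts carry coding genes only, with survival times drawn from an
exponential proportional-hazards model on the planted activities and
independent exponential censoring; segmental copy-number profiles
preferentially amplify hazardous loci / delete protective loci in the
concordant patients; and a CRISPRi-like screen assigns negative growth
phenotype scores to the planted essential set.

Every generator is a pure function of a :class:`SimulationConfig` (and the
ground truth), so identical configurations reproduce outputs exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_regulatory_cohort",
    "simulate_microarray_compendium",
    "make_gene_intervals",
    "simulate_cna_profiles",
    "simulate_essentiality_screen",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohorts.

    Defaults define the standard desk-scale cohort used throughout the test
    suite: 50 lncRNAs with ~30-gene regulons over 5,000 coding genes, 200
    RNA-seq-like samples, and a small compendium of survival cohorts.
    """

    n_lncrna: int = 50
    n_coding: int = 5000
    n_samples_rnaseq: int = 200
    n_datasets: int = 3
    samples_per_dataset: int = 150
    regulon_size_mean: int = 30
    frac_negative_edges: float = 0.3
    signal_strength: float = 1.0
    noise_sd: float = 0.5
    indep_sd: float = 0.3
    n_hazardous: int = 5
    n_protective: int = 5
    beta_magnitude: float = 0.8
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.05
    cna_bias: float = 0.9
    cna_background_rate: float = 0.15
    n_retained_lncrna: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_hazardous + self.n_protective > self.n_lncrna:
            raise ValueError("more prognostic lncRNAs than lncRNAs")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")
        if not 0 <= self.cna_bias <= 1:
            raise ValueError("cna_bias must be in [0, 1]")
        if not 0 <= self.frac_negative_edges <= 1:
            raise ValueError("frac_negative_edges must be in [0, 1]")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        for f in ("n_lncrna", "n_coding", "n_samples_rnaseq", "n_datasets",
                  "samples_per_dataset", "regulon_size_mean"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass
class GroundTruth:
    """Planted structure recorded alongside the synthetic cohorts."""

    activity: pd.DataFrame                      # lncRNA x sample
    regulons: dict[str, list[tuple[str, int, float]]]   # lnc -> (target, sign, w)
    prognostic_labels: dict[str, str]           # hazardous / protective / null
    betas: dict[str, float]
    cna_events: dict[str, list[tuple[str, int, int, int]]] = field(
        default_factory=dict
    )  # patient -> (chrom, start, end, call)
    essential_set: set[str] = field(default_factory=set)

    @property
    def hazardous(self) -> set[str]:
        return {l for l, lab in self.prognostic_labels.items()
                if lab == "hazardous"}

    @property
    def protective(self) -> set[str]:
        return {l for l, lab in self.prognostic_labels.items()
                if lab == "protective"}


def _lnc_ids(n: int) -> list[str]:
    return [f"LNC{i:04d}" for i in range(n)]


def _coding_ids(n: int) -> list[str]:
    return [f"GENE{i:05d}" for i in range(n)]


def _coding_expression(
    rng: np.random.Generator,
    activity: np.ndarray,
    regulons: dict[str, list[tuple[str, int, float]]],
    lnc_ids: list[str],
    coding_ids: list[str],
    config: SimulationConfig,
) -> np.ndarray:
    """Coding-gene matrix: planted targets track their lncRNA's activity."""
    n_samples = activity.shape[1]
    expr = config.indep_sd * rng.standard_normal(
        (len(coding_ids), n_samples)
    ) + rng.standard_normal((len(coding_ids), n_samples)) * config.noise_sd
    idx = {g: i for i, g in enumerate(coding_ids)}
    for li, lnc in enumerate(lnc_ids):
        for target, sign, w in regulons[lnc]:
            expr[idx[target]] += (
                sign * w * config.signal_strength * activity[li]
            )
    return expr


def simulate_regulatory_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """RNA-seq-like cohort containing both lncRNA and coding rows.

    lncRNA rows are their latent activity plus Gaussian noise; each planted
    target gene is sign * weight * signal_strength * activity plus an
    independent Gaussian component and noise.  Regulon target sets are
    disjoint across lncRNAs; true weights are uniform on [0.5, 1].
    """
    rng = np.random.default_rng(config.seed)
    lnc_ids = _lnc_ids(config.n_lncrna)
    coding_ids = _coding_ids(config.n_coding)
    samples = [f"S{i:04d}" for i in range(config.n_samples_rnaseq)]

    sizes = rng.poisson(config.regulon_size_mean, size=config.n_lncrna)
    sizes = np.clip(sizes, 5, None)
    if sizes.sum() > config.n_coding:
        raise ValueError("coding universe too small for requested regulons")
    pool = list(rng.permutation(coding_ids))
    regulons: dict[str, list[tuple[str, int, float]]] = {}
    cursor = 0
    for lnc, size in zip(lnc_ids, sizes):
        targets = pool[cursor:cursor + int(size)]
        cursor += int(size)
        entries = []
        for t in targets:
            sign = -1 if rng.random() < config.frac_negative_edges else 1
            w = float(rng.uniform(0.5, 1.0))
            entries.append((t, sign, w))
        regulons[lnc] = entries

    activity = rng.standard_normal((config.n_lncrna, config.n_samples_rnaseq))
    lnc_expr = activity + config.noise_sd * rng.standard_normal(activity.shape)
    coding_expr = _coding_expression(
        rng, activity, regulons, lnc_ids, coding_ids, config
    )

    expr = pd.DataFrame(
        np.vstack([lnc_expr, coding_expr]),
        index=lnc_ids + coding_ids,
        columns=samples,
    )

    order = list(rng.permutation(config.n_lncrna))
    hazard_idx = order[: config.n_hazardous]
    protect_idx = order[config.n_hazardous:
                        config.n_hazardous + config.n_protective]
    labels = {l: "null" for l in lnc_ids}
    betas = {l: 0.0 for l in lnc_ids}
    for i in hazard_idx:
        labels[lnc_ids[i]] = "hazardous"
        betas[lnc_ids[i]] = config.beta_magnitude
    for i in protect_idx:
        labels[lnc_ids[i]] = "protective"
        betas[lnc_ids[i]] = -config.beta_magnitude

    truth = GroundTruth(
        activity=pd.DataFrame(activity, index=lnc_ids, columns=samples),
        regulons=regulons,
        prognostic_labels=labels,
        betas=betas,
        essential_set={lnc_ids[i] for i in hazard_idx},
    )
    return expr, truth


def _survival_from_activity(
    rng: np.random.Generator,
    activity: np.ndarray,
    lnc_ids: list[str],
    betas: dict[str, float],
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential PH times with independent exponential censoring."""
    beta = np.array([betas[l] for l in lnc_ids])
    hazard = config.baseline_hazard * np.exp(beta @ activity)
    t_event = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / config.censoring_rate,
                                 size=len(t_event))
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(len(t_event), dtype=int)
    return time, event


def simulate_microarray_compendium(
    config: SimulationConfig, truth: GroundTruth
) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """Coding-only survival cohorts sharing the planted regulon structure.

    Each dataset draws fresh latent activities, regenerates target-gene
    expression under the same regulons, applies a per-dataset affine
    platform jitter (rank-preserving within samples), and attaches an
    exponential proportional-hazards survival table.  Optionally the first
    ``n_retained_lncrna`` lncRNA rows are kept, emulating the few lncRNAs
    with dedicated probes.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
    )
    lnc_ids = list(truth.activity.index)
    coding_ids = sorted(
        {t for entries in truth.regulons.values() for t, _, _ in entries}
        | set(_coding_ids(config.n_coding))
    )
    out = []
    for d in range(config.n_datasets):
        ds = f"DS{d:02d}"
        samples = [f"{ds}_P{i:04d}"
                   for i in range(config.samples_per_dataset)]
        activity = rng.standard_normal(
            (len(lnc_ids), config.samples_per_dataset)
        )
        coding = _coding_expression(
            rng, activity, truth.regulons, lnc_ids, coding_ids, config
        )
        scale = float(rng.uniform(0.5, 2.0))
        offset = float(rng.uniform(-1.0, 1.0))
        coding = scale * coding + offset
        rows, index = [coding], list(coding_ids)
        if config.n_retained_lncrna > 0:
            kept = lnc_ids[: config.n_retained_lncrna]
            lnc_rows = activity[: config.n_retained_lncrna]
            lnc_rows = scale * (
                lnc_rows + config.noise_sd
                * rng.standard_normal(lnc_rows.shape)
            ) + offset
            rows.append(lnc_rows)
            index = index + kept
        expr = pd.DataFrame(np.vstack(rows), index=index, columns=samples)

        time, event = _survival_from_activity(
            rng, activity, lnc_ids, truth.betas, config
        )
        surv = pd.DataFrame(
            {"sample": samples, "time": time, "event": event, "dataset": ds}
        )
        # record per-dataset activities for parameter-recovery tests
        surv.attrs["activity"] = pd.DataFrame(
            activity, index=lnc_ids, columns=samples
        )
        out.append((expr, surv))
    return out


# ---------------------------------------------------------------------------
# synthetic genome / CNA
# ---------------------------------------------------------------------------

_N_CHROMS = 5
_CHROM_LEN = 10_000_000
_SEG_LEN = 500_000


def make_gene_intervals(truth: GroundTruth) -> pd.DataFrame:
    """BED-style 0-based half-open intervals for every lncRNA.

    lncRNAs are laid out round-robin over a small fixed chromosome set, one
    per segment-sized slot, so each lncRNA falls inside exactly one CNA
    segment of :func:`simulate_cna_profiles`.
    """
    lnc_ids = list(truth.activity.index)
    slots_per_chrom = _CHROM_LEN // _SEG_LEN
    if len(lnc_ids) > _N_CHROMS * slots_per_chrom:
        raise ValueError("too many lncRNAs for the synthetic genome")
    rows = []
    for i, lnc in enumerate(lnc_ids):
        chrom = f"chr{i % _N_CHROMS + 1}"
        slot = i // _N_CHROMS
        start = slot * _SEG_LEN + _SEG_LEN // 4
        end = start + _SEG_LEN // 2
        rows.append({"gene": lnc, "chrom": chrom, "start": start,
                     "end": end, "strand": "+"})
    return pd.DataFrame(rows)


def simulate_cna_profiles(
    config: SimulationConfig,
    truth: GroundTruth,
    intervals: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Per-patient segmented copy-number profiles tiling the synthetic genome.

    With probability ``cna_bias`` the segment overlapping a hazardous locus
    is amplified (call +1, positive signal) in patients with high planted
    activity for that lncRNA, and the segment over a protective locus is
    deleted (call -1, negative signal) in low-activity patients; all
    segments additionally receive symmetric background events at
    ``cna_background_rate``.  Returns {patient: SEG-style DataFrame}.
    """
    for _, row in intervals.iterrows():
        if row.start < 0 or row.end > _CHROM_LEN or row.start >= row.end:
            raise ValueError(
                f"interval for {row.gene} outside chromosome bounds"
            )
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(2,))
    )
    patients = list(truth.activity.columns)
    seg_bounds = [
        (f"chr{c + 1}", s, s + _SEG_LEN)
        for c in range(_N_CHROMS)
        for s in range(0, _CHROM_LEN, _SEG_LEN)
    ]
    seg_index = {
        (chrom, start): k for k, (chrom, start, _) in enumerate(seg_bounds)
    }

    def segment_of(chrom: str, pos: int) -> int:
        return seg_index[(chrom, (pos // _SEG_LEN) * _SEG_LEN)]

    loci: dict[str, int] = {}
    for _, row in intervals.iterrows():
        loci[row.gene] = segment_of(row.chrom, int(row.start))

    profiles: dict[str, pd.DataFrame] = {}
    for patient in patients:
        calls = np.zeros(len(seg_bounds), dtype=int)
        bg = rng.random(len(seg_bounds))
        amp_bg = bg < config.cna_background_rate / 2
        del_bg = bg > 1 - config.cna_background_rate / 2
        calls[amp_bg] = 1
        calls[del_bg] = -1
        events: list[tuple[str, int, int, int]] = []
        # sorted iteration: set order varies across processes and would
        # change the RNG consumption order
        for lnc in sorted(truth.hazardous):
            if lnc in loci and truth.activity.loc[lnc, patient] > 0:
                if rng.random() < config.cna_bias:
                    calls[loci[lnc]] = 1
        for lnc in sorted(truth.protective):
            if lnc in loci and truth.activity.loc[lnc, patient] < 0:
                if rng.random() < config.cna_bias:
                    calls[loci[lnc]] = -1
        signal = np.where(
            calls == 1, rng.uniform(0.2, 0.8, len(calls)),
            np.where(calls == -1, -rng.uniform(0.2, 0.8, len(calls)),
                     rng.normal(0.0, 0.02, len(calls)))
        )
        rows = []
        for k, (chrom, start, end) in enumerate(seg_bounds):
            rows.append({"patient": patient, "chrom": chrom, "start": start,
                         "end": end, "signal": float(signal[k]),
                         "call": int(calls[k])})
            if calls[k] != 0:
                events.append((chrom, start, end, int(calls[k])))
        profiles[patient] = pd.DataFrame(rows)
        truth.cna_events[patient] = events
    return profiles


def simulate_essentiality_screen(
    truth: GroundTruth,
    noise_sd: float = 0.3,
    effect: float = -1.0,
    n_replicates: int = 4,
    seed: int | None = None,
) -> pd.DataFrame:
    """CRISPRi-like growth screen over the lncRNA universe.

    Planted essential lncRNAs have mean phenotype score ``effect`` (< 0 =
    growth defect on knockdown), all others 0; per-gene p-values come from a
    one-sample t-test across replicate scores.  With ``noise_sd`` 0 the
    scores are exact and p degenerates to 0 for essential genes, 1 otherwise.
    """
    rng = np.random.default_rng(seed)
    lnc_ids = list(truth.activity.index)
    unknown = truth.essential_set - set(lnc_ids)
    if unknown:
        raise ValueError(f"essential genes outside lncRNA universe: {unknown}")
    rows = []
    for lnc in lnc_ids:
        mu = effect if lnc in truth.essential_set else 0.0
        reps = mu + noise_sd * rng.standard_normal(n_replicates)
        mean = float(reps.mean())
        if reps.std(ddof=1) == 0:
            p = 0.0 if mean != 0 else 1.0
        else:
            p = float(stats.ttest_1samp(reps, 0.0).pvalue)
        rows.append({"gene": lnc, "avg_phenotype_score": mean, "p": p})
    return pd.DataFrame(rows)
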