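"""Downstream analyses of prognostic lncRNAs: threshold classification,
cross-dataset validation, essentiality overlap, per-patient copy-number
enrichment, and variance-based subtype clustering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage

from .survival import adjust_pvalues

__all__ = [
    "GeneInterval",
    "EnrichmentResult",
    "SCHEMES",
    "classify_prognostic",
    "fisher_exact_one_sided",
    "cross_dataset_validation",
    "essentiality_enrichment",
    "gene_cna_signal",
    "patient_cna_enrichment",
    "select_top_variable",
    "cluster_rows",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneInterval:
    """0-based half-open genomic interval of a gene."""

    gene: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval for {self.gene}: [{self.start}, {self.end})"
            )


@dataclass
class EnrichmentResult:
    """A 2x2 enrichment test: sample odds ratio and one-sided Fisher p."""

    table: np.ndarray
    odds_ratio: float
    p: float
    log2_or: float
    tested: bool = True
    fdr_bh: float | None = None


# ---------------------------------------------------------------------------
# prognostic classification schemes
# ---------------------------------------------------------------------------

# scheme -> (p column, cutoff, inclusive, non-prognostic rule)
SCHEMES: dict[str, dict] = {
    # meta z sign with raw meta p <= 0.1 (essentiality overlap screens)
    "precog_essentiality": {"p_col": "meta_p", "cutoff": 0.1,
                            "inclusive": True},
    # z sign with BH FDR <= 0.01 (breast-cancer CNA analysis)
    "metabric_cna": {"p_col": "fdr_bh", "cutoff": 0.01, "inclusive": True},
    # FDR < 0.05 prognostic vs FDR > 0.1 non-prognostic strata
    "cross_dataset": {"p_col": "fdr_bh", "cutoff": 0.05, "inclusive": False,
                      "nonprog_above": 0.1},
    # unadjusted p < 0.05 (CNA analysis in low-powered cohorts)
    "tcga_cna_p": {"p_col": "meta_p", "cutoff": 0.05, "inclusive": False},
    # FDR <= 0.1 variant
    "tcga_cna_fdr": {"p_col": "fdr_bh", "cutoff": 0.1, "inclusive": True},
}


def classify_prognostic(
    meta: pd.DataFrame,
    scheme: str | dict = "precog_essentiality",
    z_col: str = "meta_z",
) -> tuple[set[str], set[str], set[str]]:
    """Split lncRNAs into hazardous / protective / non-prognostic sets.

    ``meta`` is indexed by lncRNA with z and p / FDR columns.  Hazardous
    requires z > 0 and the scheme's significance rule, protective z < 0;
    under the cross-dataset scheme non-prognostic additionally requires
    FDR above its upper band, leaving the in-between lncRNAs unassigned.
    """
    if isinstance(scheme, str):
        if scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {scheme!r}")
        rule = SCHEMES[scheme]
    else:
        rule = dict(scheme)
    p = meta[rule["p_col"]].astype(float)
    z = meta[z_col].astype(float)
    sig = p <= rule["cutoff"] if rule["inclusive"] else p < rule["cutoff"]
    hazardous = set(meta.index[sig & (z > 0)])
    protective = set(meta.index[sig & (z < 0)])
    if "nonprog_above" in rule:
        nonprog = set(meta.index[p > rule["nonprog_above"]])
    else:
        nonprog = set(meta.index) - hazardous - protective
    return hazardous, protective, nonprog


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------

def fisher_exact_one_sided(table: Sequence[Sequence[int]]):
    """One-sided (enrichment / upper tail) Fisher's exact test.

    Returns (odds_ratio, p) with the sample odds ratio a*d / (b*c); a zero
    in b or c yields an infinite odds ratio, a zero in a or d a zero one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        if (t < 0).any() or not np.allclose(t, np.round(t)):
            raise ValueError("counts must be non-negative integers")
        t = t.astype(int)
    a, b, c, d = t.ravel()
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    p = float(stats.fisher_exact(t, alternative="greater")[1])
    return float(odds), p


def _enrichment(table) -> EnrichmentResult:
    odds, p = fisher_exact_one_sided(table)
    with np.errstate(divide="ignore"):
        l2 = float(np.log2(odds)) if odds == odds else np.nan
    return EnrichmentResult(table=np.asarray(table), odds_ratio=odds,
                            p=p, log2_or=l2)


def cross_dataset_validation(
    actual: pd.DataFrame,
    inferred: pd.DataFrame,
    fdr_sig: float = 0.05,
    fdr_null: float = 0.1,
) -> dict:
    """Concordance of a survival screen on actual vs inferred expression.

    Both frames are indexed by lncRNA with ``z`` (or ``meta_z``) and
    ``fdr_bh`` columns.  Reports the Pearson correlation of the two z-score
    vectors over the shared universe and, separately for the hazardous
    (z > 0) and protective (z < 0) directions, a one-sided Fisher test of
    prognostic (FDR < ``fdr_sig``) against non-prognostic (FDR >
    ``fdr_null``) lncRNAs; the in-between band is excluded.
    """
    def _cols(df):
        zc = "z" if "z" in df.columns else "meta_z"
        return df[zc].astype(float), df["fdr_bh"].astype(float)

    shared = actual.index.intersection(inferred.index)
    if len(shared) == 0:
        raise ValueError("no shared lncRNAs between the two result sets")
    za, fa = _cols(actual.loc[shared])
    zi, fi = _cols(inferred.loc[shared])
    r = float(np.corrcoef(za, zi)[0, 1])

    out = {"pearson_r": r, "n_shared": int(len(shared))}
    for direction, sign in (("hazardous", 1), ("protective", -1)):
        a_prog = (fa < fdr_sig) & (sign * za > 0)
        a_null = fa > fdr_null
        i_prog = (fi < fdr_sig) & (sign * zi > 0)
        i_null = fi > fdr_null
        a = int((a_prog & i_prog).sum())
        b = int((a_prog & i_null).sum())
        c = int((a_null & i_prog).sum())
        d = int((a_null & i_null).sum())
        out[direction] = _enrichment([[a, b], [c, d]])
    return out


def essentiality_enrichment(
    hazardous: Iterable[str],
    protective: Iterable[str],
    screen: pd.DataFrame,
    score_cutoff: float = 0.0,
    p_cutoff: float = 0.1,
) -> dict[str, EnrichmentResult]:
    """Overlap of prognostic lncRNAs with growth-essential lncRNAs.

    Essential means average phenotype score below ``score_cutoff`` (growth
    defect on knockdown) with screen p <= ``p_cutoff``.  For each direction
    the 2x2 table is {direction set, rest of screened universe} x
    {essential, non-essential}, tested one-sided for enrichment.
    """
    universe = set(screen["gene"])
    if not universe:
        raise ValueError("empty screen")
    essential = set(
        screen.loc[
            (screen["avg_phenotype_score"] < score_cutoff)
            & (screen["p"] <= p_cutoff),
            "gene",
        ]
    )
    out = {}
    for name, group in (("hazardous", set(hazardous)),
                        ("protective", set(protective))):
        grp = group & universe
        rest = universe - grp
        a = len(grp & essential)
        b = len(grp - essential)
        c = len(rest & essential)
        d = len(rest - essential)
        out[name] = _enrichment([[a, b], [c, d]])
    return out


# ---------------------------------------------------------------------------
# copy-number analyses
# ---------------------------------------------------------------------------

def _overlaps(interval, seg_start: int, seg_end: int) -> bool:
    return interval.start < seg_end and seg_start < interval.end


def gene_cna_signal(
    interval: GeneInterval,
    profile: pd.DataFrame,
    length_weighted: bool = False,
) -> float:
    """Copy-number signal of a gene: mean signal of overlapping segments.

    The default is the unweighted mean over every segment with a nonzero
    half-open intersection; ``length_weighted`` weights each segment by its
    overlap length instead.  No overlapping segment (or an unknown
    chromosome) yields NaN.
    """
    sub = profile[profile["chrom"] == interval.chrom]
    if sub.empty:
        warnings.warn(f"chromosome {interval.chrom} absent from profile")
        return float("nan")
    mask = (interval.start < sub["end"]) & (sub["start"] < interval.end)
    hits = sub[mask]
    if hits.empty:
        return float("nan")
    if length_weighted:
        ov = (
            np.minimum(hits["end"], interval.end)
            - np.maximum(hits["start"], interval.start)
        ).to_numpy(dtype=float)
        return float(np.average(hits["signal"], weights=ov))
    return float(hits["signal"].mean())


def patient_cna_enrichment(
    hazardous: Iterable[str],
    protective: Iterable[str],
    intervals: pd.DataFrame,
    profiles: Mapping[str, pd.DataFrame],
    direction: str = "amplification",
    min_cell: int = 5,
) -> dict[str, EnrichmentResult]:
    """Per-patient enrichment of prognostic lncRNAs in called CNA segments.

    A lncRNA counts as altered when any overlapping segment carries the
    direction's call (+1 amplification, -1 deletion).  The table is
    {concordant class, discordant class} x {altered, not}; the concordant
    class is hazardous for amplification and protective for deletion.  A
    patient is tested only when every cell has at least ``min_cell`` counts;
    BH adjustment runs across tested patients only.
    """
    hazardous, protective = set(hazardous), set(protective)
    if not hazardous or not protective:
        raise ValueError("both prognostic sets must be nonempty")
    call = {"amplification": 1, "deletion": -1}.get(direction)
    if call is None:
        raise ValueError(f"unknown direction {direction!r}")
    itable = intervals.set_index("gene")
    missing = (hazardous | protective) - set(itable.index)
    if missing:
        raise ValueError(f"prognostic lncRNAs without intervals: {missing}")

    first = hazardous if call == 1 else protective
    second = protective if call == 1 else hazardous

    results: dict[str, EnrichmentResult] = {}
    for patient, prof in profiles.items():
        called = prof[prof["call"] == call]

        def altered(genes):
            out = set()
            for g in genes:
                row = itable.loc[g]
                sub = called[called["chrom"] == row.chrom]
                if ((row.start < sub["end"])
                        & (sub["start"] < row.end)).any():
                    out.add(g)
            return out

        alt1 = altered(first)
        alt2 = altered(second)
        a = len(alt1)
        b = len(first) - a
        c = len(alt2)
        d = len(second) - c
        res = _enrichment([[a, b], [c, d]])
        res.tested = min(a, b, c, d) >= min_cell
        results[patient] = res

    tested = [p for p, r in results.items() if r.tested]
    if tested:
        adj = adjust_pvalues([results[p].p for p in tested], "BH")
        for p, q in zip(tested, adj):
            results[p].fdr_bh = float(q)
    return results


# ---------------------------------------------------------------------------
# subtype clustering
# ---------------------------------------------------------------------------

def select_top_variable(iexpr: pd.DataFrame, k: int = 500) -> pd.DataFrame:
    """Keep the k rows with the highest across-sample variance.

    Ties break by gene id; if k exceeds the row count all rows are kept
    with a warning.
    """
    if k > len(iexpr):
        warnings.warn(
            f"k={k} exceeds {len(iexpr)} rows; keeping all rows"
        )
        k = len(iexpr)
    var = iexpr.var(axis=1, ddof=1)
    order = sorted(iexpr.index, key=lambda g: (-var[g], g))
    return iexpr.loc[order[:k]]


def cluster_rows(
    matrix: pd.DataFrame,
    method: str = "complete",
    metric: str = "euclidean",
) -> tuple[np.ndarray, list[str]]:
    """Gene-wise agglomerative clustering after row z-transformation.

    Rows are standardised to mean 0 / sd 1 across samples (zero-variance
    rows are excluded with a warning), then clustered with the requested
    linkage and metric.  Returns the scipy linkage matrix and the leaf-order
    gene list.
    """
    from scipy.cluster.hierarchy import leaves_list

    vals = matrix.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero-variance rows")
    vals = vals[keep]
    genes = [g for g, k in zip(matrix.index, keep) if k]
    if len(genes) < 2:
        raise ValueError("need at least 2 non-constant rows")
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    Z = linkage(z, method=method, metric=metric)
    order = [genes[i] for i in leaves_list(Z)]
    return Z, order
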