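"""Cancer-specific lncRNA regulon inference.

Builds a mutual-information (MI) network between lncRNA regulators and
candidate target genes, prunes indirect edges with the data processing
inequality (DPI), stabilises the network by bootstrap consensus, and converts
each regulator's edge set into signed, max-normalised weight profiles suitable
for rank-based expression imputation.

The MI estimators act on within-vector ranks, so every score is exactly
invariant under strictly monotone transforms of either input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MINetwork",
    "Regulon",
    "RegulonWeightProfiles",
    "RegulonModel",
    "RegulonResults",
    "estimate_mi",
    "mi_threshold",
    "apply_dpi",
    "bootstrap_consensus",
    "build_regulon",
    "make_weight_profiles",
]

log = logging.getLogger(__name__)

# chi-square critical value, 3 d.f., alpha = 0.05 (adaptive-partition stop rule)
_CHI2_CRIT = stats.chi2.isf(0.05, df=3)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MINetwork:
    """Undirected regulator-anchored MI network.

    ``edges`` maps an (a, b) pair (order as inserted, no duplicates either
    way) to its MI in nats; ``bootstrap_support`` counts, per edge, the number
    of bootstrap networks containing it.
    """

    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    bootstrap_support: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (a, b), mi in self.edges.items():
            if a == b:
                raise ValueError(f"self-edge {a!r}")
            if mi < 0:
                raise ValueError(f"negative MI on edge ({a}, {b})")

    def canonical(self) -> dict[frozenset, float]:
        return {frozenset(e): mi for e, mi in self.edges.items()}

    def neighbors(self, node: str) -> set[str]:
        out = set()
        for a, b in self.edges:
            if a == node:
                out.add(b)
            elif b == node:
                out.add(a)
        return out

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class Regulon:
    """A lncRNA with signed, max-normalised target weights.

    ``targets`` maps gene id -> (weight in (0, 1], sign in {+1, -1}).  The
    maximum weight over targets is exactly 1 by construction.
    """

    lncrna: str
    targets: dict[str, tuple[float, int]]

    def __post_init__(self) -> None:
        if self.lncrna in self.targets:
            raise ValueError("regulon must not contain its own regulator")
        if self.targets:
            wmax = max(w for w, _ in self.targets.values())
            if not np.isclose(wmax, 1.0):
                raise ValueError("max target weight must equal 1")


@dataclass
class RegulonWeightProfiles:
    """Non-negative up/down weight profiles over the gene universe.

    ``up`` carries positive-sign target weights, ``down`` the magnitudes of
    negative-sign weights; supports are disjoint.  A profile with fewer than
    ``min_genes`` nonzero entries is flagged invalid and contributes nothing
    downstream.
    """

    lncrna: str
    up: dict[str, float]
    down: dict[str, float]
    up_valid: bool
    down_valid: bool
    min_genes: int = 20

    @property
    def inferable(self) -> bool:
        return self.up_valid or self.down_valid


# ---------------------------------------------------------------------------
# MI estimation
# ---------------------------------------------------------------------------

def _rank_positions(x: np.ndarray) -> np.ndarray:
    """0..n-1 positions of each element in the stable ascending sort."""
    order = np.argsort(x, kind="stable")
    pos = np.empty_like(order)
    pos[order] = np.arange(len(x))
    return pos


def _equifreq_bin_ids(x: np.ndarray, bins: int) -> np.ndarray:
    return (_rank_positions(x) * bins) // len(x)


def _bin_marginal_counts(n: int, bins: int) -> np.ndarray:
    ids = (np.arange(n) * bins) // n
    return np.bincount(ids, minlength=bins)


def _mi_from_joint(counts: np.ndarray) -> float:
    """Plug-in MI (nats) from a joint count table."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * np.log(p / (px * py))
    return float(np.nansum(term))


def _mi_equifreq(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    bx = _equifreq_bin_ids(x, bins)
    by = _equifreq_bin_ids(y, bins)
    joint = np.zeros((bins, bins), dtype=np.int64)
    np.add.at(joint, (bx, by), 1)
    return _mi_from_joint(joint)


def _mi_adaptive(x: np.ndarray, y: np.ndarray, min_points: int = 8) -> float:
    """Adaptive-partitioning plug-in MI on rank-transformed data.

    Recursively splits the rank plane into quadrants while a chi-square test
    (3 d.f., alpha 0.05) rejects uniformity of the quadrant counts; each leaf
    contributes p*log(p / (wx*wy)).
    """
    n = len(x)
    px = _rank_positions(x).astype(float)
    py = _rank_positions(y).astype(float)

    total = 0.0
    # stack of (x0, x1, y0, y1, index-array) over rank space [0, n)^2
    stack = [(0.0, float(n), 0.0, float(n), np.arange(n))]
    while stack:
        x0, x1, y0, y1, idx = stack.pop()
        m = len(idx)
        wx = (x1 - x0) / n
        wy = (y1 - y0) / n
        if m == 0:
            continue
        leaf = True
        if m >= min_points and (x1 - x0) > 1 and (y1 - y0) > 1:
            xm = (x0 + x1) / 2.0
            ym = (y0 + y1) / 2.0
            right = px[idx] >= xm
            top = py[idx] >= ym
            q = [
                idx[~right & ~top],
                idx[~right & top],
                idx[right & ~top],
                idx[right & top],
            ]
            counts = np.array([len(qq) for qq in q], dtype=float)
            expected = m / 4.0
            chi2 = float(((counts - expected) ** 2 / expected).sum())
            if chi2 > _CHI2_CRIT:
                leaf = False
                stack.append((x0, xm, y0, ym, q[0]))
                stack.append((x0, xm, ym, y1, q[1]))
                stack.append((xm, x1, y0, ym, q[2]))
                stack.append((xm, x1, ym, y1, q[3]))
        if leaf:
            p = m / n
            total += p * np.log(p / (wx * wy))
    return max(0.0, total)


def estimate_mi(
    x: Sequence[float],
    y: Sequence[float],
    estimator: str = "adaptive_partition",
    bins: int = 4,
) -> float:
    """Mutual information (nats) between two sample vectors.

    Both estimators operate on ranks and are therefore exactly invariant to
    strictly monotone transforms of either input.  A constant vector carries
    no information and yields MI = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 8:
        raise ValueError("need at least 8 samples to estimate MI")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    if estimator == "equifreq_bins":
        return _mi_equifreq(x, y, bins)
    if estimator == "adaptive_partition":
        return _mi_adaptive(x, y)
    raise ValueError(f"unknown estimator {estimator!r}")


def _mi_matrix_equifreq(
    regs: np.ndarray, genes: np.ndarray, bins: int
) -> np.ndarray:
    """Vectorised equal-frequency MI between every regulator row and gene row.

    ``regs`` is (r, n), ``genes`` (g, n); returns an (r, g) MI matrix.  Joint
    counts are accumulated cell-by-cell with boolean matrix products, and both
    marginals are the deterministic equal-frequency bin sizes.
    """
    r, n = regs.shape
    g = genes.shape[0]
    reg_bins = np.vstack([_equifreq_bin_ids(row, bins) for row in regs])
    gene_bins = np.vstack([_equifreq_bin_ids(row, bins) for row in genes])
    marg = _bin_marginal_counts(n, bins).astype(float)

    mi = np.zeros((r, g))
    gene_ind = [
        (gene_bins == j).astype(np.float64) for j in range(bins)
    ]  # each (g, n)
    for i in range(bins):
        a = (reg_bins == i).astype(np.float64)  # (r, n)
        for j in range(bins):
            cij = a @ gene_ind[j].T  # (r, g) joint counts
            pij = cij / n
            with np.errstate(divide="ignore", invalid="ignore"):
                term = pij * np.log(cij * n / (marg[i] * marg[j]))
            mi += np.where(cij > 0, term, 0.0)
    return np.maximum(mi, 0.0)


# ---------------------------------------------------------------------------
# significance threshold and DPI
# ---------------------------------------------------------------------------

def mi_threshold(
    n_samples: int,
    p_value: float = 0.01,
    n_null: int = 1000,
    seed: int | None = None,
    estimator: str = "equifreq_bins",
    bins: int = 4,
    bootstrap: bool = False,
) -> float:
    """Empirical (1 - p_value) null MI quantile for independent vectors.

    The null is built from MI between pairs of independently permuted rank
    vectors of the requested length.  With ``bootstrap`` the null pair is
    additionally subjected to a shared with-replacement resampling of the
    sample indices, matching the duplicate-sample structure of a bootstrap
    draw (repeated joint observations bias plug-in MI upward, so the
    threshold must be calibrated on the same structure).
    """
    if not 0 < p_value <= 1:
        raise ValueError("p_value must be in (0, 1]")
    if n_null < 1.0 / p_value:
        raise ValueError("n_null too small for the requested quantile")
    rng = np.random.default_rng(seed)
    base = np.arange(n_samples, dtype=float)

    def draw_pair():
        x = rng.permutation(base)
        y = rng.permutation(base)
        if bootstrap:
            cols = rng.integers(0, n_samples, size=n_samples)
            x = x[cols] + rng.standard_normal(n_samples) * 1e-9
            y = y[cols] + rng.standard_normal(n_samples) * 1e-9
        return x, y

    if estimator == "equifreq_bins":
        nulls = np.array(
            [_mi_equifreq(*draw_pair(), bins) for _ in range(n_null)]
        )
    else:
        nulls = np.array(
            [
                estimate_mi(*draw_pair(), estimator=estimator, bins=bins)
                for _ in range(n_null)
            ]
        )
    nulls.sort()
    idx = int(np.floor((1.0 - p_value) * n_null))
    idx = min(idx, n_null - 1)
    return float(nulls[idx])


def apply_dpi(network: MINetwork, tolerance: float = 0.0) -> MINetwork:
    """Prune indirect edges with the data processing inequality.

    In every fully connected triple, the weakest edge is removed when its MI
    falls below (1 - tolerance) times the smaller of the other two.  Removal
    decisions are made simultaneously against the input network.
    """
    if not 0 <= tolerance < 1:
        raise ValueError("tolerance must be in [0, 1)")
    canon = network.canonical()
    adj: dict[str, set[str]] = {}
    for a, b in network.edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    doomed: set[frozenset] = set()
    for (a, b), mi_ab in network.edges.items():
        common = adj[a] & adj[b]
        for c in common:
            other = min(canon[frozenset((a, c))], canon[frozenset((b, c))])
            if mi_ab < (1.0 - tolerance) * other:
                doomed.add(frozenset((a, b)))
                break
    kept = {e: mi for e, mi in network.edges.items()
            if frozenset(e) not in doomed}
    support = {e: s for e, s in network.bootstrap_support.items() if e in kept}
    return MINetwork(edges=kept, bootstrap_support=support)


# ---------------------------------------------------------------------------
# bootstrap consensus
# ---------------------------------------------------------------------------

def bootstrap_consensus(
    expr: pd.DataFrame,
    regulators: Sequence[str],
    n_bootstrap: int = 100,
    mi_p: float = 0.01,
    consensus_p: float = 0.05,
    seed: int | None = None,
    estimator: str = "equifreq_bins",
    bins: int = 4,
    dpi_tolerance: float = 0.0,
    n_null: int = 1000,
    consensus_mode: str = "poisson",
    min_support_fraction: float = 0.5,
) -> MINetwork:
    """Bootstrap-consensus MI network over a gene-by-sample matrix.

    Each bootstrap resamples samples with replacement, thresholds pairwise MI
    at the permutation-null ``mi_p`` quantile and applies DPI; edges whose
    support across bootstraps is significant under a Poisson null (mean =
    total edge occurrences / distinct edges, Bonferroni at ``consensus_p``)
    survive, carrying the mean MI over their supporting bootstraps.
    """
    genes = list(expr.index)
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene ids")
    missing = set(regulators) - set(genes)
    if missing:
        raise ValueError(f"regulators absent from matrix: {sorted(missing)}")
    n = expr.shape[1]
    if n < 8:
        raise ValueError("need at least 8 samples")
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    if estimator != "equifreq_bins":
        raise NotImplementedError(
            "bootstrap consensus uses the vectorised equal-frequency "
            "estimator; use estimate_mi for adaptive partitioning"
        )

    rng = np.random.default_rng(seed)
    values = expr.to_numpy(dtype=float)
    reg_idx = np.array([genes.index(r) for r in regulators])
    gene_arr = np.array(genes)
    regulator_set = set(regulators)

    thresh = mi_threshold(
        n, p_value=mi_p, n_null=n_null,
        seed=int(rng.integers(2**31)), estimator="equifreq_bins", bins=bins,
        bootstrap=True,
    )

    support: dict[tuple[str, str], int] = {}
    mi_sum: dict[tuple[str, str], float] = {}
    scale = values.std() if values.std() > 0 else 1.0
    for _ in range(n_bootstrap):
        cols = rng.integers(0, n, size=n)
        boot = values[:, cols]
        # resampling duplicates samples; identical columns would share rank
        # order across every pair of rows, biasing rank-based MI upward, so
        # ties are broken by a vanishing random jitter
        boot = boot + rng.standard_normal(boot.shape) * (1e-9 * scale)
        mi = _mi_matrix_equifreq(boot[reg_idx], boot, bins)  # (r, g)
        edges: dict[tuple[str, str], float] = {}
        seen: set[frozenset] = set()
        ri, gi = np.nonzero(mi >= thresh)
        for a, b, m in zip(reg_idx[ri], gi, mi[ri, gi]):
            ga, gb = gene_arr[a], gene_arr[b]
            if ga == gb:
                continue
            key = frozenset((ga, gb))
            if key in seen:
                continue
            seen.add(key)
            edges[(ga, gb)] = float(m)
        net = apply_dpi(MINetwork(edges=edges), tolerance=dpi_tolerance)
        for e, m in net.edges.items():
            key = _canon_pair(e, regulator_set)
            support[key] = support.get(key, 0) + 1
            mi_sum[key] = mi_sum.get(key, 0.0) + m

    if n_bootstrap == 1:
        final = {e: mi_sum[e] for e in support}
        return MINetwork(edges=final, bootstrap_support=dict(support))

    distinct = len(support)
    if distinct == 0:
        return MINetwork()
    lam = sum(support.values()) / distinct
    if consensus_mode == "poisson":
        alpha = consensus_p / distinct
        edges_list = list(support)
        counts = np.array([support[e] for e in edges_list])
        sf = stats.poisson.sf(counts - 1, lam)
        keep = {e for e, pv in zip(edges_list, sf) if pv < alpha}
    elif consensus_mode == "fraction":
        keep = {
            e for e, s in support.items()
            if s / n_bootstrap >= min_support_fraction
        }
    else:
        raise ValueError(f"unknown consensus_mode {consensus_mode!r}")
    final = {e: mi_sum[e] / support[e] for e in keep}
    return MINetwork(
        edges=final, bootstrap_support={e: support[e] for e in keep}
    )


def _canon_pair(edge: tuple[str, str], regulators: set[str]) -> tuple[str, str]:
    """Orient an edge regulator-first (lexicographic within a role class)."""
    a, b = edge
    a_reg, b_reg = a in regulators, b in regulators
    if a_reg and not b_reg:
        return (a, b)
    if b_reg and not a_reg:
        return (b, a)
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# regulons and weight profiles
# ---------------------------------------------------------------------------

def build_regulon(network: MINetwork, expr: pd.DataFrame, lncrna: str) -> Regulon:
    """Signed, max-normalised regulon of one lncRNA.

    Weights are MI divided by the regulon's maximum MI; the sign is the sign
    of the Pearson correlation between the lncRNA's expression and the
    target's.  Targets with exactly zero correlation are dropped.
    """
    incident = {
        (b if a == lncrna else a): mi
        for (a, b), mi in network.edges.items()
        if lncrna in (a, b)
    }
    if not incident:
        raise KeyError(f"{lncrna!r} has no edges in the network")
    if lncrna not in expr.index:
        raise KeyError(f"{lncrna!r} not in expression matrix")
    max_mi = max(incident.values())
    x = expr.loc[lncrna].to_numpy(dtype=float)
    targets: dict[str, tuple[float, int]] = {}
    for gene, mi in incident.items():
        y = expr.loc[gene].to_numpy(dtype=float)
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if r == 0.0:
            continue
        targets[gene] = (mi / max_mi, 1 if r > 0 else -1)
    return Regulon(lncrna=lncrna, targets=targets)


def make_weight_profiles(
    regulon: Regulon,
    gene_universe: Sequence[str],
    min_genes: int = 20,
) -> RegulonWeightProfiles:
    """Split a signed regulon into non-negative up/down weight profiles.

    Positive-sign targets populate the up profile, magnitudes of
    negative-sign targets the down profile.  A profile with fewer than
    ``min_genes`` nonzero entries is invalid and treated as all-zero; when
    both are invalid the lncRNA is non-inferable.
    """
    universe = set(gene_universe)
    outside = set(regulon.targets) - universe
    if outside:
        raise ValueError(
            f"targets outside gene universe: {sorted(outside)[:5]}"
        )
    up = {g: w for g, (w, s) in regulon.targets.items() if s > 0}
    down = {g: w for g, (w, s) in regulon.targets.items() if s < 0}
    return RegulonWeightProfiles(
        lncrna=regulon.lncrna,
        up=up,
        down=down,
        up_valid=len(up) >= min_genes,
        down_valid=len(down) >= min_genes,
        min_genes=min_genes,
    )


# ---------------------------------------------------------------------------
# model facade
# ---------------------------------------------------------------------------

class RegulonModel:
    """Regulon network model over a gene-by-sample expression matrix.

    Parameters
    ----------
    expr : pandas.DataFrame
        Genes in rows, samples in columns; values already normalised.
    regulators : sequence of str
        lncRNA gene ids to anchor the network on (must be rows of ``expr``).
    """

    def __init__(self, expr: pd.DataFrame, regulators: Sequence[str]):
        if expr.index.has_duplicates or expr.columns.has_duplicates:
            raise ValueError("duplicate gene or sample ids")
        if not np.isfinite(expr.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        self.expr = expr
        self.regulators = list(regulators)
        missing = set(self.regulators) - set(expr.index)
        if missing:
            raise ValueError(f"regulators not in matrix: {sorted(missing)}")

    @classmethod
    def from_dataframe(cls, expr: pd.DataFrame, regulators: Sequence[str]):
        return cls(expr, regulators)

    def fit(
        self,
        n_bootstrap: int = 100,
        mi_p: float = 0.01,
        consensus_p: float = 0.05,
        min_genes: int = 20,
        seed: int | None = None,
        **kwargs,
    ) -> "RegulonResults":
        network = bootstrap_consensus(
            self.expr,
            self.regulators,
            n_bootstrap=n_bootstrap,
            mi_p=mi_p,
            consensus_p=consensus_p,
            seed=seed,
            **kwargs,
        )
        regulons: dict[str, Regulon] = {}
        profiles: dict[str, RegulonWeightProfiles] = {}
        universe = list(self.expr.index)
        for lnc in self.regulators:
            try:
                reg = build_regulon(network, self.expr, lnc)
            except KeyError:
                continue
            if not reg.targets:
                continue
            regulons[lnc] = reg
            profiles[lnc] = make_weight_profiles(
                reg, universe, min_genes=min_genes
            )
        return RegulonResults(self, network, regulons, profiles)


class RegulonResults:
    """Fitted regulon network: edges, per-lncRNA regulons, weight profiles."""

    def __init__(self, model, network, regulons, profiles):
        self.model = model
        self.network = network
        self.regulons = regulons
        self.profiles = profiles

    def summary(self) -> pd.DataFrame:
        rows = []
        for lnc, prof in self.profiles.items():
            rows.append(
                {
                    "lncrna": lnc,
                    "n_targets": len(self.regulons[lnc].targets),
                    "n_up": len(prof.up),
                    "n_down": len(prof.down),
                    "up_valid": prof.up_valid,
                    "down_valid": prof.down_valid,
                    "inferable": prof.inferable,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "lncrna", "n_targets", "n_up", "n_down",
                "up_valid", "down_valid", "inferable",
            ],
        ).set_index("lncrna")
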