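"""Hydrogen-exchange protection factors from per-structure hydrogen-bond counts.

Four per-structure protection models combine the protein and water
hydrogen-bond counts of an amide site, all built on the idea that a site is
more protected the more hydrogen bonds it forms with the protein and the
fewer with water. With NH = min(HB_p, 1) and NW = min(HB_w, 1):

    park             f = b * NH            (base parameter b, default 500)
    ratio            f = HB_p / max(HB_w, 1)
    difference       f = HB_p - HB_w
    bound_difference f = NH - NW           (only values 1, 0 or -1)

Per-cluster protection factors PF_ij are means of f over structures sampled
from the cluster with equilibrium frame weights; the ensemble PF_i is the
population-weighted average over the most populated clusters (the five most
populated by default).

In the EX2 regime of the classical two-state exchange model
(closed <-> open, exchange from open at the intrinsic rate k_int), the
observed exchange rate is the intrinsic rate attenuated by the protection
factor PF = k_cl / k_op: k_obs = k_int / PF, valid when k_cl >> k_int.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .hbonds import HBondCounts

logger = logging.getLogger(__name__)

__all__ = [
    "PF_MODELS",
    "PFModelSpec",
    "PFTable",
    "ExchangeKinetics",
    "pf_structure",
    "pf_cluster",
    "pf_ensemble",
    "protection_factor_table",
    "compare_experimental",
    "variable_sites",
    "ex2_observed_rate",
    "pf_from_rates",
]

PF_MODELS = ("park", "ratio", "difference", "bound_difference")


@dataclass(frozen=True)
class PFModelSpec:
    """Protection model selection; ``b`` is the Park-model base parameter.

    Historically b spans 1e4-1e6; the default 500 keeps the maximum
    attainable protection factor of order the largest measured values.
    """

    model: str = "park"
    b: float = 500.0

    def __post_init__(self) -> None:
        if self.model not in PF_MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {PF_MODELS}")
        if self.b <= 0:
            raise ValueError("base parameter b must be positive")


def pf_structure(hb_p, hb_w, spec: PFModelSpec | None = None) -> np.ndarray:
    """Per-structure protection f for given hydrogen-bond counts.

    Accepts scalars or arrays (broadcast together); counts must be
    nonnegative integers.
    """
    spec = spec or PFModelSpec()
    hb_p = np.asarray(hb_p)
    hb_w = np.asarray(hb_w)
    if np.any(hb_p < 0) or np.any(hb_w < 0):
        raise ValueError("hydrogen-bond counts must be nonnegative")
    if not (
        np.issubdtype(hb_p.dtype, np.integer) or np.all(hb_p == np.round(hb_p))
    ) or not (
        np.issubdtype(hb_w.dtype, np.integer) or np.all(hb_w == np.round(hb_w))
    ):
        raise ValueError("hydrogen-bond counts must be integers")
    p = hb_p.astype(float)
    w = hb_w.astype(float)
    nh = np.minimum(p, 1.0)
    nw = np.minimum(w, 1.0)
    if spec.model == "park":
        out = spec.b * nh
    elif spec.model == "ratio":
        out = p / np.maximum(w, 1.0)
    elif spec.model == "difference":
        out = p - w
    else:  # bound_difference
        out = nh - nw
    return out


def pf_cluster(
    counts: HBondCounts,
    cluster_labels: np.ndarray,
    weights: np.ndarray,
    spec: PFModelSpec | None = None,
    n_sample: int = 4000,
    seed: int = 0,
    clusters: list[int] | None = None,
) -> pd.DataFrame:
    """Mean per-site protection PF_ij per cluster from weighted resampling.

    For each cluster, draws ``n_sample`` frames with probability
    proportional to the equilibrium frame weights (with replacement when the
    cluster holds fewer frames than n_sample, which is logged) and averages
    the per-structure f values. Deterministic given ``seed``. Returns a
    (site x cluster) table.
    """
    spec = spec or PFModelSpec()
    labels = np.asarray(cluster_labels)
    weights = np.asarray(weights, dtype=float)
    if len(labels) != counts.n_frames or len(weights) != counts.n_frames:
        raise ValueError("labels/weights must have one entry per frame")
    if n_sample < 1:
        raise ValueError("n_sample must be >= 1")
    if clusters is None:
        clusters = sorted(int(c) for c in np.unique(labels))

    table = {}
    for j in clusters:
        idx = np.flatnonzero(labels == j)
        if len(idx) == 0:
            raise ValueError(f"cluster {j} is empty")
        w = weights[idx]
        if w.sum() <= 0:
            w = np.ones(len(idx))
        w = w / w.sum()
        n_support = int((w > 0).sum())
        replace = n_support < n_sample
        if replace:
            logger.info(
                "cluster %s has %d positive-weight frames < n_sample=%d; "
                "sampling with replacement",
                j,
                n_support,
                n_sample,
            )
        rng = np.random.default_rng([seed, int(j)])
        sampled = rng.choice(idx, size=n_sample, replace=replace, p=w)
        f = pf_structure(counts.hb_p[sampled], counts.hb_w[sampled], spec)
        table[j] = f.mean(axis=0)
    return pd.DataFrame(table, index=pd.Index(counts.sites, name="site"))


def pf_ensemble(
    pf_ij: pd.DataFrame,
    cluster_populations,
    included_clusters: list[int] | None = None,
) -> pd.Series:
    """Ensemble PF_i: population-weighted average of PF_ij over included clusters.

    ``cluster_populations`` maps cluster label -> population (dict, Series,
    or array indexed by label). By default the five most populated clusters
    present in ``pf_ij`` are included; their populations are renormalized to
    sum to 1.
    """
    pops = pd.Series(
        dict(enumerate(cluster_populations))
        if isinstance(cluster_populations, (list, np.ndarray, tuple))
        else dict(cluster_populations)
    )
    if included_clusters is None:
        candidates = [c for c in pf_ij.columns if c in pops.index]
        included_clusters = list(
            pops.loc[candidates].sort_values(ascending=False).index[:5]
        )
    w = pops.loc[list(included_clusters)].astype(float)
    if np.any(w <= 0):
        raise ValueError("included clusters must have positive population")
    w = w / w.sum()
    out = (pf_ij[list(included_clusters)] * w).sum(axis=1)
    out.name = "PF"
    return out


@dataclass
class PFTable:
    """Per-cluster and ensemble protection factors plus the settings used."""

    per_cluster: pd.DataFrame
    ensemble: pd.Series
    cluster_weights: pd.Series
    model: PFModelSpec
    criteria: object
    n_sample: int

    def summary(self, experimental: pd.Series | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"PF": self.ensemble})
        if experimental is not None:
            df["experimental"] = experimental
            df["residual"] = df["PF"] - df["experimental"]
        return df


def protection_factor_table(
    counts: HBondCounts,
    cluster_labels: np.ndarray,
    weights: np.ndarray,
    cluster_populations,
    spec: PFModelSpec | None = None,
    n_sample: int = 4000,
    seed: int = 0,
    included_clusters: list[int] | None = None,
) -> PFTable:
    """Full PF bookkeeping: PF_ij per cluster plus the weighted ensemble PF_i."""
    spec = spec or PFModelSpec()
    per_cluster = pf_cluster(
        counts, cluster_labels, weights, spec, n_sample=n_sample, seed=seed
    )
    ens = pf_ensemble(per_cluster, cluster_populations, included_clusters)
    pops = pd.Series(
        dict(enumerate(cluster_populations))
        if isinstance(cluster_populations, (list, np.ndarray, tuple))
        else dict(cluster_populations)
    )
    return PFTable(
        per_cluster=per_cluster,
        ensemble=ens,
        cluster_weights=pops,
        model=spec,
        criteria=counts.criteria,
        n_sample=n_sample,
    )


@dataclass
class ComparisonResult:
    pearson_r: float
    n_shared: int
    residuals: pd.Series
    unmatched_computed: list[str]
    unmatched_experimental: list[str]


def compare_experimental(pf_i: pd.Series, experimental: pd.Series) -> ComparisonResult:
    """Pearson correlation and residuals against an experimental PF table.

    Site labels (chain+residue strings such as "A11") must match exactly;
    sites present in only one table are reported as unmatched. At least 3
    shared sites are required.
    """
    pf_i = pd.Series(pf_i)
    experimental = pd.Series(experimental)
    shared = pf_i.index.intersection(experimental.index)
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared sites after label matching; need >= 3"
        )
    a = pf_i.loc[shared].astype(float)
    b = experimental.loc[shared].astype(float)
    r, _ = pearsonr(a, b)
    return ComparisonResult(
        pearson_r=float(r),
        n_shared=len(shared),
        residuals=a - b,
        unmatched_computed=list(pf_i.index.difference(experimental.index)),
        unmatched_experimental=list(experimental.index.difference(pf_i.index)),
    )


def variable_sites(
    pf_ij: pd.DataFrame,
    criterion: str = "variance_ratio",
    threshold: float | None = None,
) -> list[str]:
    """Sites whose protection varies strongly across clusters.

    criterion="variance_ratio": flag when the population variance of PF_ij
    over clusters is at least ``threshold`` (default 10) times the mean;
    sites with nonpositive mean are skipped (logged). criterion="cv": flag
    when the coefficient of variation (std/mean) is >= ``threshold``
    (default 0.10).
    """
    if pf_ij.shape[1] < 2:
        raise ValueError("need at least 2 clusters")
    if criterion not in ("variance_ratio", "cv"):
        raise ValueError(f"unknown criterion {criterion!r}")
    thr = threshold if threshold is not None else (10.0 if criterion == "variance_ratio" else 0.10)
    flagged = []
    for site, row in pf_ij.iterrows():
        vals = row.to_numpy(dtype=float)
        mean = vals.mean()
        if mean <= 0:
            logger.info("variable_sites: site %s skipped (nonpositive mean)", site)
            continue
        var = vals.var()  # population variance
        if criterion == "variance_ratio":
            if var >= thr * mean:
                flagged.append(site)
        else:
            if np.sqrt(var) / mean >= thr:
                flagged.append(site)
    return flagged


# ---------------------------------------------------------------------------
# exchange kinetics (EX2 regime)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExchangeKinetics:
    """Two-state exchange rates: closed <-> open, exchange at k_int when open."""

    k_op: float
    k_cl: float
    k_int: float
    ex2_threshold: float = 100.0

    def __post_init__(self) -> None:
        if min(self.k_op, self.k_cl, self.k_int) <= 0:
            raise ValueError("all rates must be positive")

    @property
    def pf(self) -> float:
        """Protection factor PF = k_cl / k_op."""
        return self.k_cl / self.k_op

    @property
    def ex2_valid(self) -> bool:
        """EX2 requires closing much faster than intrinsic exchange."""
        return self.k_cl >= self.ex2_threshold * self.k_int


def ex2_observed_rate(kin: ExchangeKinetics) -> float:
    """Observed exchange rate in the EX2 limit: k_obs = k_int / PF.

    Warns (without refusing) when the EX2 validity condition
    k_cl >> k_int does not hold.
    """
    if not kin.ex2_valid:
        warnings.warn(
            f"EX2 approximation questionable: k_cl/k_int = "
            f"{kin.k_cl / kin.k_int:.3g} < {kin.ex2_threshold:g}",
            RuntimeWarning,
            stacklevel=2,
        )
    return kin.k_int / kin.pf


def pf_from_rates(k_obs: float, k_int: float) -> float:
    """Invert the EX2 relation: PF = k_int / k_obs."""
    if k_obs <= 0 or k_int <= 0:
        raise ValueError("rates must be positive")
    return k_int / k_obs
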