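"""Sex-association scan: impute, thin, test, permute, and bound the SDR.

The per-SNP test mirrors a TASSEL-style GLM for a binary phenotype:
ordinary least-squares regression of sex (F=1, M=0) on alt-allele dosage,
with the p-value from the F statistic on (1, n-2) degrees of freedom.
Kinship (centered IBS) is computed and reported but not included in the
model, matching the GLM's actual semantics.  Experiment-wise significance
comes from the empirical alpha-quantile of minimum p-values over
permutations of the sex labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CohortPanel, VariantTable

__all__ = [
    "DosageMatrix",
    "AssocResult",
    "dosage_from_table",
    "knn_impute",
    "thin_by_interval",
    "glm_assoc",
    "permutation_threshold",
    "centered_ibs",
    "sdr_bounds",
    "two_stage_scan",
]


@dataclass
class DosageMatrix:
    """samples x sites alt-dosage matrix ({0,1,2} or NaN) with site metadata."""

    values: np.ndarray  # (n_samples, n_sites) float
    sites: pd.DataFrame  # columns scaffold, pos
    samples: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.sites = pd.DataFrame(
            self.sites, columns=["scaffold", "pos"]
        ).reset_index(drop=True)
        if self.values.shape != (len(self.samples), len(self.sites)):
            raise ValueError("dosage shape does not match samples/sites")

    def subset_sites(self, index) -> "DosageMatrix":
        idx = np.arange(self.values.shape[1])[index]
        return DosageMatrix(self.values[:, idx], self.sites.iloc[idx],
                            list(self.samples))


@dataclass
class AssocResult:
    """Per-site association statistics plus the permutation threshold."""

    table: pd.DataFrame  # scaffold, pos, stat, p, neglog10p, tested
    threshold: float | None = None


def dosage_from_table(table: VariantTable) -> DosageMatrix:
    return DosageMatrix(
        values=table.dosage().T,
        sites=table.sites[["scaffold", "pos"]],
        samples=list(table.samples),
    )


def knn_impute(matrix: DosageMatrix, k: int = 5) -> DosageMatrix:
    """Fill missing dosages from the k nearest samples.

    Sample-sample distance is the mean squared dosage difference over sites
    observed in both (root taken -- a Euclidean distance normalised for
    unequal overlap).  A missing entry becomes the mean dosage of the k
    globally nearest samples observed at that site, rounded to the nearest
    integer in {0,1,2}; observed entries are untouched.  Sites missing in
    every sample are left missing (and warned about) so callers can exclude
    them.
    """
    x = matrix.values
    n, m = x.shape
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    obs = ~np.isnan(x)
    if not obs.any(axis=1).all():
        raise ValueError("a sample has no observed sites")
    x0 = np.nan_to_num(x, nan=0.0)
    # pairwise mean squared difference over mutually observed sites
    shared = obs.astype(float) @ obs.T.astype(float)
    sq = (x0 ** 2) * obs
    cross = x0 @ x0.T
    ssq = sq @ obs.T.astype(float)
    d2 = ssq + ssq.T - 2 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.sqrt(d2 / shared)
    np.fill_diagonal(dist, np.inf)
    dist[shared == 0] = np.inf
    order = np.argsort(dist, axis=1, kind="stable")
    neighbors = order[:, :k]  # (n, k)

    out = x.copy()
    nb_vals = x[neighbors, :]  # (n, k, m)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        nb_mean = np.nanmean(nb_vals, axis=1)  # (n, m)
        site_mean = np.nanmean(np.where(obs, x, np.nan), axis=0)  # (m,)
    fill = np.where(np.isnan(nb_mean), site_mean[None, :], nb_mean)
    fill = np.clip(np.round(fill), 0, 2)
    miss = np.isnan(x)
    out[miss] = fill[miss]
    all_missing = ~obs.any(axis=0)
    if all_missing.any():
        import warnings

        warnings.warn(
            f"{all_missing.sum()} site(s) missing in every sample were left "
            "unimputed", stacklevel=2,
        )
        out[:, all_missing] = np.nan
    return DosageMatrix(out, matrix.sites, list(matrix.samples))


def thin_by_interval(sites: pd.DataFrame, interval: int = 5000,
                     seed: int = 0) -> np.ndarray:
    """One uniformly chosen site per non-empty ``interval``-base window.

    Windows are [i*interval+1, (i+1)*interval] per scaffold.  Returns the
    sorted indices (into ``sites``) of the retained subset; seeded and
    reproducible.
    """
    rng = np.random.default_rng(seed)
    sites = pd.DataFrame(sites)
    window = (sites["pos"].to_numpy() - 1) // interval
    keys = pd.DataFrame({
        "scaffold": sites["scaffold"].to_numpy(),
        "window": window,
        "idx": np.arange(len(sites)),
    })
    chosen = []
    for _, grp in keys.groupby(["scaffold", "window"], sort=False):
        chosen.append(int(rng.choice(grp["idx"].to_numpy())))
    return np.sort(np.array(chosen, dtype=int))


def _f_test(y: np.ndarray, x: np.ndarray):
    """Vectorised per-column OLS F-test of y on each column of x.

    Returns (F statistics, p-values, tested mask); monomorphic columns are
    untested (NaN statistics).
    """
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 samples")
    yc = y - y.mean()
    xc = x - x.mean(axis=0)
    sxx = (xc ** 2).sum(axis=0)
    tested = sxx > 0
    syy = float((yc ** 2).sum())
    sxy = yc @ xc
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(tested, (sxy ** 2) / np.where(tested, sxx, 1.0) / syy,
                      np.nan)
    r2 = np.clip(r2, 0.0, 1.0)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        f = r2 * df / (1.0 - r2)
    p = stats.f.sf(f, 1, df)
    # perfect fits underflow: report the smallest positive double instead of 0
    p = np.where(np.isinf(f), np.nextafter(0, 1), p)
    return f, p, tested


def glm_assoc(matrix: DosageMatrix, panel: CohortPanel) -> AssocResult:
    """Per-site GLM (OLS F-test) of sex on imputed dosage."""
    y = panel.sex_vector(matrix.samples)
    x = matrix.values
    if np.isnan(x).any():
        raise ValueError("dosage matrix must be imputed (no missing values)")
    f, p, tested = _f_test(y, x)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(p)
    out = matrix.sites.copy()
    out["stat"] = f
    out["p"] = p
    out["neglog10p"] = neglog
    out["tested"] = tested
    out.loc[~tested, ["stat", "p", "neglog10p"]] = np.nan
    return AssocResult(table=out)


def permutation_threshold(matrix: DosageMatrix, panel: CohortPanel,
                          n_perm: int = 1000, alpha: float = 0.05,
                          seed: int = 0) -> float:
    """Experiment-wise p threshold from permuted sex labels.

    The threshold is the k-th smallest per-permutation minimum p with
    k = max(1, floor(alpha * (n_perm + 1))), so a fresh null minimum falls
    below it with probability ~= alpha.
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    y = panel.sex_vector(matrix.samples)
    x = matrix.values
    if np.isnan(x).any():
        raise ValueError("dosage matrix must be imputed (no missing values)")
    n = len(y)
    xc = x - x.mean(axis=0)
    sxx = (xc ** 2).sum(axis=0)
    tested = sxx > 0
    xc = xc[:, tested]
    sxx = sxx[tested]
    minp = np.empty(n_perm)
    df = n - 2
    for b in range(n_perm):
        yp = rng.permutation(y)
        yc = yp - yp.mean()
        syy = float((yc ** 2).sum())
        r2 = np.clip((yc @ xc) ** 2 / sxx / syy, 0.0, 1.0)
        with np.errstate(divide="ignore"):
            f = r2 * df / (1.0 - r2)
        p = stats.f.sf(f, 1, df)
        p = np.where(np.isinf(f), np.nextafter(0, 1), p)
        minp[b] = p.min()
    k = max(1, int(np.floor(alpha * (n_perm + 1))))
    return float(np.sort(minp)[k - 1])


def centered_ibs(matrix: DosageMatrix) -> pd.DataFrame:
    """VanRaden-style centered identity-by-state kinship matrix.

    Dosages are centered by twice the alt-allele frequency; the
    cross-product matrix is scaled by sum(2 p (1-p)) over sites.
    """
    x = matrix.values
    if np.isnan(x).any():
        raise ValueError("dosage matrix must be imputed (no missing values)")
    p = x.mean(axis=0) / 2.0
    w = x - 2.0 * p
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom == 0:
        raise ValueError("all sites monomorphic; kinship undefined")
    k = (w @ w.T) / denom
    return pd.DataFrame(k, index=matrix.samples, columns=matrix.samples)


def sdr_bounds(assoc: AssocResult, scaffold: str,
               p_cut: float = 1e-7):
    """[min, max] position of sites with p <= p_cut on ``scaffold``.

    A p equal to the cutoff counts as significant.  Returns None when no
    site passes.
    """
    df = assoc.table
    hit = df[(df["scaffold"] == scaffold) & (df["p"] <= p_cut)
             & df["tested"]]
    if hit.empty:
        return None
    return int(hit["pos"].min()), int(hit["pos"].max())


def candidate_scaffolds(assoc: AssocResult, p_cut: float = 1e-3,
                        min_hits: int = 3, span: int = 100_000) -> list:
    """Scaffolds with >= ``min_hits`` significant sites within ``span`` bases.

    Operationalises "multiple co-linear significant SNPs" for the two-stage
    genome scan.
    """
    df = assoc.table
    sig = df[(df["p"] <= p_cut) & df["tested"]]
    out = []
    for scaffold, grp in sig.groupby("scaffold", sort=False):
        pos = np.sort(grp["pos"].to_numpy())
        if len(pos) >= min_hits:
            window = pos[min_hits - 1:] - pos[: len(pos) - min_hits + 1]
            if np.any(window <= span):
                out.append(scaffold)
    return out


def two_stage_scan(table: VariantTable, panel: CohortPanel,
                   thin_interval: int = 5000, n_perm: int = 1000,
                   alpha: float = 0.05, p_cut_stage1: float = 1e-3,
                   p_cut_bounds: float = 1e-7, seed: int = 0,
                   knn_k: int = 5):
    """Thinned genome-wide pass, then full-density pass per candidate scaffold.

    Returns a dict with the thinned-pass result (including the permutation
    threshold), candidate scaffolds, per-candidate full-density results, and
    the SDR interval from the strongest candidate (None when nothing
    passes).
    """
    from .io_formats import keep_biallelic

    bi = keep_biallelic(table)
    thin_idx = thin_by_interval(bi.sites, interval=thin_interval, seed=seed)
    thinned = dosage_from_table(bi.subset(thin_idx))
    thinned = knn_impute(thinned, k=knn_k)
    stage1 = glm_assoc(thinned, panel)
    stage1.threshold = permutation_threshold(
        thinned, panel, n_perm=n_perm, alpha=alpha, seed=seed + 1
    )
    cands = candidate_scaffolds(stage1, p_cut=p_cut_stage1)
    full_results, bounds = {}, {}
    for scaffold in cands:
        mask = (bi.sites["scaffold"] == scaffold).to_numpy()
        dense = knn_impute(dosage_from_table(bi.subset(mask)), k=knn_k)
        res = glm_assoc(dense, panel)
        full_results[scaffold] = res
        b = sdr_bounds(res, scaffold, p_cut=p_cut_bounds)
        if b is not None:
            bounds[scaffold] = b
    best = None
    if bounds:
        # strongest candidate: smallest minimum p among its sites
        best = min(
            bounds,
            key=lambda sc: float(np.nanmin(full_results[sc].table["p"])),
        )
    return {
        "stage1": stage1,
        "candidates": cands,
        "full": full_results,
        "bounds": bounds,
        "sdr_scaffold": best,
        "sdr_interval": bounds.get(best) if best else None,
    }
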