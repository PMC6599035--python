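"""Differential protein abundance between sinus node and atrium.

The procedure mirrors the Perseus label-free workflow: collapse isoforms to
the most abundant representative, drop decoy/contaminant rows, keep proteins
with at least ``min_valid_per_group`` quantified values in one tissue and at
least ``min_peptides`` peptides, quantile-normalize, impute left-censored
missing values from a downshifted per-sample normal (width 0.3, downshift
1.8 SD), and test with an S0-moderated two-sample t statistic under a
permutation-based FDR (SAM/Tusher style) at q = 0.05 with 750 balanced
relabelings (exhaustive whenever fewer distinct relabelings exist).

The steps that transform an :class:`~sinode.containers.IntensityMatrix` are
scikit-learn style transformers (``fit``/``transform``, ``get_params``), so
they compose in an :class:`sklearn.pipeline.Pipeline`; the volcano test is an
estimator whose fitted state carries the per-protein results table. Plain
functions wrapping each estimator are provided for one-shot use.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import IntensityMatrix

__all__ = [
    "ImputationParams",
    "VolcanoConfig",
    "IsoformCollapser",
    "ValidValueFilter",
    "QuantileNormalizer",
    "DownshiftImputer",
    "PermutationFDRVolcano",
    "collapse_isoforms",
    "filter_proteins",
    "quantile_normalize",
    "impute_downshift",
    "moderated_t",
    "permutation_fdr",
    "imputation_sanity_check",
    "ibaq_rank",
]


@dataclass
class ImputationParams:
    """Downshifted-normal imputation parameters (Perseus convention).

    ``width_w`` is the imputation SD as a fraction of the per-sample SD of
    observed values; ``downshift_d`` shifts the imputation mean down by that
    many per-sample SDs.
    """

    width_w: float = 0.3
    downshift_d: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_w <= 0:
            raise ValueError("width_w must be > 0")
        if self.downshift_d < 0:
            raise ValueError("downshift_d must be >= 0")


@dataclass
class VolcanoConfig:
    """Configuration of the moderated-t permutation-FDR volcano analysis."""

    s0: float = 0.1
    n_permutations: int = 750
    fdr_q: float = 0.05
    min_valid_per_group: int = 3
    min_peptides: int = 2
    permuted_count: str = "mean"  # or "median" (SAM's original convention)
    #: pseudo-count added to the permuted exceedance count before dividing
    #: (Phipson-Smyth-style guard). Without it, a protein whose |d| happens
    #: to beat every permuted value gets estimated FDR 0 regardless of how
    #: few distinct relabelings a 3v3 design affords, which is
    #: anti-conservative under the null. Set to 0 for the raw ratio.
    fdr_numerator_offset: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.s0 < 0:
            raise ValueError("s0 must be >= 0")
        if self.permuted_count not in ("mean", "median"):
            raise ValueError("permuted_count must be 'mean' or 'median'")
        if self.fdr_numerator_offset < 0:
            raise ValueError("fdr_numerator_offset must be >= 0")


# ---------------------------------------------------------------------------
# isoform collapse & filtering
# ---------------------------------------------------------------------------


class IsoformCollapser(BaseEstimator, TransformerMixin):
    """Keep one row per isoform group and drop decoy/contaminant rows.

    Within each isoform group the row with the highest summed intensity
    (missing treated as zero) is retained, the convention used when protein
    groups representing isoforms of one canonical protein are collapsed.
    """

    def fit(self, X: IntensityMatrix, y=None):
        return self

    def transform(self, X: IntensityMatrix) -> IntensityMatrix:
        keep = pd.Series(True, index=X.protein_ids)
        if X.reverse_flag is not None:
            keep &= ~X.reverse_flag.astype(bool)
        if X.contaminant_flag is not None:
            keep &= ~X.contaminant_flag.astype(bool)
        m = X.subset(X.protein_ids[keep])
        if m.isoform_group is None:
            return m
        totals = m.values.fillna(0.0).sum(axis=1)
        order = pd.DataFrame({"group": m.isoform_group, "total": totals})
        # idxmax breaks exact ties by first occurrence, keeping this
        # deterministic under a stable input order
        winners = order.groupby("group", sort=False)["total"].idxmax()
        kept_ids = [pid for pid in m.protein_ids if pid in set(winners)]
        return m.subset(kept_ids)


class ValidValueFilter(BaseEstimator, TransformerMixin):
    """Retain proteins with >= ``min_valid_per_group`` values in SN *or* RA
    and >= ``min_peptides`` identified peptides."""

    def __init__(self, min_valid_per_group: int = 3, min_peptides: int = 2):
        self.min_valid_per_group = min_valid_per_group
        self.min_peptides = min_peptides

    def fit(self, X: IntensityMatrix, y=None):
        return self

    def transform(self, X: IntensityMatrix) -> IntensityMatrix:
        groups = X.groups
        sizes = {g: len(X.samples_in_group(g)) for g in groups}
        if all(n < self.min_valid_per_group for n in sizes.values()):
            raise ValueError(
                f"fewer samples than min_valid_per_group={self.min_valid_per_group} "
                f"in every group: {sizes}"
            )
        present = X.values.notna()
        ok = pd.Series(False, index=X.protein_ids)
        for g in groups:
            ok |= present[X.samples_in_group(g)].sum(axis=1) >= self.min_valid_per_group
        if X.peptide_counts is not None:
            ok &= X.peptide_counts >= self.min_peptides
        return X.subset(X.protein_ids[ok])


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Force every sample onto the across-sample mean order-statistic grid.

    Complete samples end up with identical sorted value vectors. Samples with
    missing values keep their missingness pattern; their observed values are
    mapped through the reference quantile function at their fractional ranks
    (the interpolation convention limma's ``normalizeQuantiles`` uses).
    """

    def fit(self, X: IntensityMatrix, y=None):
        return self

    def transform(self, X: IntensityMatrix) -> IntensityMatrix:
        if X.n_samples < 2:
            raise ValueError("quantile normalization needs at least 2 samples")
        vals = X.values.to_numpy(dtype=float)
        n = vals.shape[0]
        for j, s in enumerate(X.samples):
            if np.isnan(vals[:, j]).all():
                raise ValueError(f"sample {s!r} has no observed values")
        grid = np.linspace(0.0, 1.0, n)
        # reference distribution: mean across samples of each sample's
        # empirical quantile function on a common grid
        ref = np.zeros(n)
        for j in range(vals.shape[1]):
            obs = vals[~np.isnan(vals[:, j]), j]
            ref += np.quantile(obs, grid)
        ref /= vals.shape[1]

        out = np.full_like(vals, np.nan)
        for j in range(vals.shape[1]):
            col = vals[:, j]
            mask = ~np.isnan(col)
            obs = col[mask]
            ranks = sps.rankdata(obs, method="average")  # ties -> mean rank
            if obs.size == 1:
                p = np.array([0.5])
            else:
                p = (ranks - 1.0) / (obs.size - 1.0)
            out[mask, j] = np.interp(p, grid, ref)
        return X.with_values(
            pd.DataFrame(out, index=X.values.index, columns=X.values.columns)
        )


# ---------------------------------------------------------------------------
# downshifted imputation
# ---------------------------------------------------------------------------


class DownshiftImputer(BaseEstimator, TransformerMixin):
    """Impute missing values from a downshifted normal, per sample.

    For sample ``s`` with observed mean ``mu_s`` and SD ``sigma_s``, each
    missing entry is drawn from
    ``Normal(mu_s - downshift * sigma_s, (width * sigma_s)^2)`` — the
    left-censored imputation appropriate for MNAR proteomics dropout.
    Observed entries are never touched. After :meth:`transform`,
    ``imputed_mask_`` holds the boolean mask of filled entries.
    """

    def __init__(self, width: float = 0.3, downshift: float = 1.8, random_state: int = 0):
        self.width = width
        self.downshift = downshift
        self.random_state = random_state

    def fit(self, X: IntensityMatrix, y=None):
        ImputationParams(self.width, self.downshift, self.random_state)  # validate
        return self

    def transform(self, X: IntensityMatrix) -> IntensityMatrix:
        self.fit(X)
        rng = np.random.default_rng(self.random_state)
        vals = X.values.to_numpy(dtype=float).copy()
        mask = np.isnan(vals)
        for j, s in enumerate(X.samples):
            obs = vals[~mask[:, j], j]
            if obs.size < 2:
                raise ValueError(f"sample {s!r} has fewer than 2 observed values")
            mu, sigma = obs.mean(), obs.std(ddof=1)
            k = int(mask[:, j].sum())
            if k:
                vals[mask[:, j], j] = rng.normal(
                    mu - self.downshift * sigma, self.width * sigma, size=k
                )
        self.imputed_mask_ = pd.DataFrame(
            mask, index=X.values.index, columns=X.values.columns
        )
        return X.with_values(
            pd.DataFrame(vals, index=X.values.index, columns=X.values.columns)
        )


# ---------------------------------------------------------------------------
# moderated t statistic
# ---------------------------------------------------------------------------


def _pooled_se(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sample pooled-variance standard error, vectorized over rows."""
    nx, ny = x.shape[-1], y.shape[-1]
    vx = x.var(axis=-1, ddof=1)
    vy = y.var(axis=-1, ddof=1)
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    return np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))


def moderated_t(x, y, s0: float = 0.1) -> tuple[float, float]:
    """S0-moderated two-sample statistic and unmoderated Student p-value.

    ``d = (mean(x) - mean(y)) / (se_pooled + s0)``; the additive ``s0``
    (SAM's fudge factor) damps significance of low-variance proteins whose
    fold change is negligible. The p-value comes from the *unmoderated*
    two-sided Student t test with pooled variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 values per group")
    se = _pooled_se(x, y)
    if se == 0 and s0 == 0:
        raise ZeroDivisionError("zero variance in both groups with s0 = 0")
    diff = x.mean() - y.mean()
    d = diff / (se + s0)
    if se == 0:
        p = 0.0 if diff != 0 else 1.0
    else:
        t = diff / se
        p = 2.0 * sps.t.sf(abs(t), x.size + y.size - 2)
    return float(d), float(p)


def _d_stats(vals: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, s0: float) -> np.ndarray:
    """Moderated d for every row at once for one label assignment."""
    x, y = vals[:, idx_a], vals[:, idx_b]
    return (x.mean(axis=1) - y.mean(axis=1)) / (_pooled_se(x, y) + s0)


def _balanced_assignments(n_samples: int, n_a: int, original: tuple | None = None):
    """Distinct ways to pick which columns play group A.

    The original labeling and (for equal group sizes) its complement are
    excluded: they reproduce the observed statistics and would floor the
    estimated FDR at 2/n_relabelings, making 5% FDR unreachable in a 3v3
    design.
    """
    out = []
    for c in itertools.combinations(range(n_samples), n_a):
        if original is not None:
            if c == original:
                continue
            comp = tuple(i for i in range(n_samples) if i not in c)
            if comp == original:
                continue
        out.append(np.array(c))
    return out


# ---------------------------------------------------------------------------
# permutation FDR (Tusher / SAM symmetric threshold)
# ---------------------------------------------------------------------------


class PermutationFDRVolcano(BaseEstimator):
    """Permutation-FDR volcano analysis of a complete intensity matrix.

    Fits the Tusher-style procedure: observed ``|d|`` per protein, balanced
    group-label relabelings (exhaustive when the number of distinct balanced
    relabelings does not exceed ``n_permutations``, sampled without
    replacement otherwise), and the symmetric threshold

    ``FDR(t) = (E_perm[#{|d_perm| >= t}] + offset) / #{|d_obs| >= t}``

    with the significance set the largest threshold-set whose estimated FDR
    stays at or below ``fdr_q``. The original labeling and its mirror are
    never used as permutations, and the default ``offset = 1`` pseudo-count
    keeps the estimate conservative in the extreme tail, where a 3v3 design
    offers only 18 distinct relabelings.

    Fitted attributes
    -----------------
    results_ : pandas.DataFrame
        Per protein: ``log2fc`` (mean SN - mean RA), ``d_stat``, ``p_value``,
        ``significant``, ``direction``, imputed counts per group if a mask
        was supplied.
    threshold_ : float
        The |d| cut; ``inf`` when nothing is significant.
    fdr_curve_ : pandas.DataFrame
        Candidate thresholds with permuted/observed counts and FDR estimate.
    exhaustive_ : bool
        Whether relabelings were enumerated exhaustively.
    """

    def __init__(
        self,
        s0: float = 0.1,
        n_permutations: int = 750,
        fdr_q: float = 0.05,
        permuted_count: str = "mean",
        fdr_numerator_offset: float = 1.0,
        random_state: int = 0,
    ):
        self.s0 = s0
        self.n_permutations = n_permutations
        self.fdr_q = fdr_q
        self.permuted_count = permuted_count
        self.fdr_numerator_offset = fdr_numerator_offset
        self.random_state = random_state

    def fit(self, X: IntensityMatrix, y=None, imputed_mask: pd.DataFrame | None = None):
        cfg = VolcanoConfig(
            s0=self.s0,
            n_permutations=self.n_permutations,
            fdr_q=self.fdr_q,
            permuted_count=self.permuted_count,
            fdr_numerator_offset=self.fdr_numerator_offset,
        )
        self.warnings_: list[str] = []
        if self.n_permutations < 10:
            msg = f"n_permutations={self.n_permutations} < 10: FDR estimate unstable"
            self.warnings_.append(msg)
            warnings.warn(msg)
        vals = X.values.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError("volcano analysis requires a complete (imputed) matrix")
        groups = X.groups
        if len(groups) != 2:
            raise ValueError(f"need exactly 2 groups, got {groups}")
        cols = list(X.samples)
        idx_a = np.array([cols.index(s) for s in X.samples_in_group(groups[0])])
        idx_b = np.array([cols.index(s) for s in X.samples_in_group(groups[1])])

        d_obs = _d_stats(vals, idx_a, idx_b, self.s0)
        # unmoderated Student p (pooled variance, two-sided)
        se = _pooled_se(vals[:, idx_a], vals[:, idx_b])
        diff = vals[:, idx_a].mean(axis=1) - vals[:, idx_b].mean(axis=1)
        df = idx_a.size + idx_b.size - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, diff / np.where(se > 0, se, 1.0), np.inf * np.sign(diff))
        p = 2.0 * sps.t.sf(np.abs(tstat), df)
        p = np.where(se > 0, p, np.where(diff == 0, 1.0, 0.0))

        assignments = _balanced_assignments(len(cols), idx_a.size, original=tuple(idx_a))
        n_distinct = len(assignments)
        self.exhaustive_ = n_distinct <= self.n_permutations
        rng = np.random.default_rng(self.random_state)
        if self.exhaustive_:
            chosen = assignments
        else:
            pick = rng.choice(n_distinct, size=self.n_permutations, replace=False)
            chosen = [assignments[i] for i in pick]

        all_idx = np.arange(len(cols))
        perm_abs = np.empty((len(chosen), vals.shape[0]))
        for i, a in enumerate(chosen):
            b = np.setdiff1d(all_idx, a)
            perm_abs[i] = np.abs(_d_stats(vals, a, b, self.s0))

        abs_obs = np.abs(d_obs)
        # candidate thresholds: the observed |d| values themselves
        cand = np.unique(abs_obs)[::-1]  # descending: tightest first
        obs_counts = np.array([(abs_obs >= t).sum() for t in cand])
        reducer = np.mean if self.permuted_count == "mean" else np.median
        perm_counts = np.array(
            [reducer((perm_abs >= t).sum(axis=1)) for t in cand], dtype=float
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            fdr = (perm_counts + self.fdr_numerator_offset) / obs_counts
        self.fdr_curve_ = pd.DataFrame(
            {"threshold": cand, "observed_count": obs_counts,
             "permuted_count": perm_counts, "fdr": fdr}
        )
        ok = fdr <= self.fdr_q
        if ok.any():
            # the largest significance set (smallest threshold) still under q
            self.threshold_ = float(cand[np.where(ok)[0].max()])
        else:
            self.threshold_ = math.inf

        significant = abs_obs >= self.threshold_
        direction = np.where(
            significant, np.where(d_obs > 0, f"{groups[0]}-higher", f"{groups[1]}-higher"), "none"
        )
        res = pd.DataFrame(
            {
                "log2fc": diff,
                "d_stat": d_obs,
                "p_value": p,
                "significant": significant,
                "direction": direction,
            },
            index=X.protein_ids,
        )
        if imputed_mask is not None:
            for g, gi in ((groups[0], idx_a), (groups[1], idx_b)):
                res[f"imputed_{g}"] = imputed_mask.to_numpy()[:, gi].sum(axis=1)
        res["flagged_by_sanity_check"] = False
        self.results_ = res
        self.groups_ = groups
        self.n_significant_ = int(significant.sum())
        return self


# ---------------------------------------------------------------------------
# post-hoc imputation sanity check
# ---------------------------------------------------------------------------


def imputation_sanity_check(
    result: pd.DataFrame,
    raw_matrix: IntensityMatrix,
    imputed_matrix: IntensityMatrix,
    imputed_mask: pd.DataFrame,
    max_log2_deviation: float = 2.0,
) -> pd.Series:
    """Flag significant proteins whose call may rest on imputation.

    Re-examines every significant protein with <= 2 quantified values in
    either group: if the between-group log2 ratio computed from the raw
    (pre-imputation) observed intensities deviates from the post-imputation
    ratio by more than ``max_log2_deviation``, the protein is flagged (never
    silently removed). Proteins with no raw evidence in one group keep their
    flag set, since their fold change is pure imputation.
    """
    groups = raw_matrix.groups
    mask = imputed_mask.to_numpy()
    raw = raw_matrix.values
    imp = imputed_matrix.values
    flags = pd.Series(False, index=result.index)
    cols = {g: raw_matrix.samples_in_group(g) for g in groups}
    for pid in result.index[result["significant"]]:
        n_valid = {g: int(raw.loc[pid, cols[g]].notna().sum()) for g in groups}
        if all(v >= 3 for v in n_valid.values()):
            continue
        raw_means = {g: raw.loc[pid, cols[g]].mean() for g in groups}
        imp_means = {g: imp.loc[pid, cols[g]].mean() for g in groups}
        if any(pd.isna(raw_means[g]) for g in groups):
            flags[pid] = True
            continue
        raw_ratio = raw_means[groups[0]] - raw_means[groups[1]]
        imp_ratio = imp_means[groups[0]] - imp_means[groups[1]]
        if abs(raw_ratio - imp_ratio) > max_log2_deviation or (
            np.sign(raw_ratio) != np.sign(imp_ratio) and raw_ratio != 0
        ):
            flags[pid] = True
    return flags


# ---------------------------------------------------------------------------
# iBAQ abundance ranking
# ---------------------------------------------------------------------------


def ibaq_rank(ibaq: pd.Series) -> pd.DataFrame:
    """Rank proteins from lowest to highest mean abundance.

    Returns ascending ranks (ties get the mean of covered ranks) and the
    percentile ``rank / N`` — the most abundant protein sits at 1.0.
    """
    ibaq = pd.Series(ibaq, dtype=float)
    if (ibaq < 0).any():
        raise ValueError("iBAQ intensities must be non-negative")
    ranks = pd.Series(sps.rankdata(ibaq.to_numpy(), method="average"), index=ibaq.index)
    return pd.DataFrame({"rank": ranks, "percentile": ranks / len(ibaq)})


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def collapse_isoforms(matrix: IntensityMatrix) -> IntensityMatrix:
    return IsoformCollapser().fit(matrix).transform(matrix)


def filter_proteins(matrix: IntensityMatrix, config: VolcanoConfig | None = None) -> IntensityMatrix:
    cfg = config or VolcanoConfig()
    return ValidValueFilter(cfg.min_valid_per_group, cfg.min_peptides).fit(matrix).transform(matrix)


def quantile_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    return QuantileNormalizer().fit(matrix).transform(matrix)


def impute_downshift(
    matrix: IntensityMatrix, params: ImputationParams | None = None
) -> tuple[IntensityMatrix, pd.DataFrame]:
    p = params or ImputationParams()
    imp = DownshiftImputer(p.width_w, p.downshift_d, p.seed)
    out = imp.fit(matrix).transform(matrix)
    return out, imp.imputed_mask_


def permutation_fdr(
    matrix: IntensityMatrix,
    config: VolcanoConfig | None = None,
    seed: int = 0,
    imputed_mask: pd.DataFrame | None = None,
) -> PermutationFDRVolcano:
    cfg = config or VolcanoConfig()
    est = PermutationFDRVolcano(
        s0=cfg.s0,
        n_permutations=cfg.n_permutations,
        fdr_q=cfg.fdr_q,
        permuted_count=cfg.permuted_count,
        fdr_numerator_offset=cfg.fdr_numerator_offset,
        random_state=seed,
    )
    return est.fit(matrix, imputed_mask=imputed_mask)
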