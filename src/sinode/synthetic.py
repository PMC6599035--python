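"""Synthetic proteomics benchmarks with known ground truth.

Two generators cover the pipeline's inputs:

* a 2-group (SN vs RA) label-free intensity matrix — log-normal abundances,
  a designated differential subset with known log2 effect sizes, and
  abundance-dependent (MNAR, missing-not-at-random) dropout following a
  logistic left-censoring curve, the standard proteomics assumption;
* an iBAQ channel table built backwards from known channel copy numbers and
  a subunit stoichiometry, so the copy-number estimator can be validated by
  round-trip.

All randomness flows through ``numpy.random.default_rng`` (PCG64), so a fixed
seed gives bit-identical output across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GROUP_RA, GROUP_SN, GroundTruth, IntensityMatrix


@dataclass
class SyntheticProteomeConfig:
    """Parameters of the synthetic 2-group proteome.

    Attributes
    ----------
    n_proteins, n_differential : int
        Total rows and how many are truly differential (``n_differential <=
        n_proteins``). Differential proteins are the first rows, alternating
        SN-higher / RA-higher.
    n_replicates_per_group : int
        Biological replicates per tissue; the study design is 3 vs 3.
    log2_effect_size : float
        Mean SN-minus-RA shift (log2 units) for differential proteins; split
        symmetrically as +/- half per group.
    base_mean, base_sd : float
        Mean and SD (log2 units) of the per-protein abundance distribution.
    noise_sd : float
        Within-group residual SD (log2 units) of replicate measurements.
    mnar_midpoint : float
        Log2 intensity at which the dropout probability is 0.5.
    mnar_steepness : float
        Logistic steepness (1 / log2 unit); larger = sharper censoring.
    seed : int
        PCG64 seed.
    """

    n_proteins: int = 5000
    n_differential: int = 250
    n_replicates_per_group: int = 3
    log2_effect_size: float = 2.0
    base_mean: float = 25.0
    base_sd: float = 2.5
    noise_sd: float = 0.3
    mnar_midpoint: float = 20.5
    mnar_steepness: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0 or self.n_replicates_per_group <= 0:
            raise ValueError("n_proteins and n_replicates_per_group must be positive")
        if not 0 <= self.n_differential <= self.n_proteins:
            raise ValueError("need 0 <= n_differential <= n_proteins")
        if self.base_sd <= 0 or self.noise_sd < 0:
            raise ValueError("base_sd must be > 0 and noise_sd >= 0")


def mnar_missing_probability(x: np.ndarray, config: SyntheticProteomeConfig) -> np.ndarray:
    """Dropout probability p(x) = 1 / (1 + exp(k * (x - m))).

    Decreasing in intensity ``x``: faint proteins are preferentially lost,
    which is what motivates downshifted imputation downstream.
    """
    z = config.mnar_steepness * (np.asarray(x, dtype=float) - config.mnar_midpoint)
    return 1.0 / (1.0 + np.exp(z))


def generate_intensity_matrix(
    config: SyntheticProteomeConfig,
) -> tuple[IntensityMatrix, GroundTruth]:
    """Draw a complete (pre-missingness) log2 intensity matrix.

    Protein ``i``, sample ``j`` is ``Normal(mu_i + s_ij, noise_sd^2)`` with
    ``mu_i ~ Normal(base_mean, base_sd^2)`` and ``s_ij = +/- effect/2`` by
    group for differential proteins (0 otherwise).
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_proteins, config.n_replicates_per_group
    protein_ids = pd.Index([f"P{i:05d}" for i in range(n)], name="protein")
    samples = [f"SN{j + 1}" for j in range(k)] + [f"RA{j + 1}" for j in range(k)]
    group_labels = pd.Series([GROUP_SN] * k + [GROUP_RA] * k, index=samples)

    true_log2fc = np.zeros(n)
    diff = np.zeros(n, dtype=bool)
    diff[: config.n_differential] = True
    # alternate direction so neither tissue is systematically brighter
    signs = np.where(np.arange(config.n_differential) % 2 == 0, 1.0, -1.0)
    true_log2fc[: config.n_differential] = signs * config.log2_effect_size

    mu = rng.normal(config.base_mean, config.base_sd, size=n)
    shift = np.zeros((n, 2 * k))
    shift[:, :k] = (true_log2fc / 2)[:, None]
    shift[:, k:] = (-true_log2fc / 2)[:, None]
    vals = rng.normal(mu[:, None] + shift, config.noise_sd)

    values = pd.DataFrame(vals, index=protein_ids, columns=samples)
    matrix = IntensityMatrix(
        values=values,
        group_labels=group_labels,
        peptide_counts=pd.Series(rng.integers(2, 30, size=n), index=protein_ids),
        reverse_flag=pd.Series(False, index=protein_ids),
        contaminant_flag=pd.Series(False, index=protein_ids),
        isoform_group=pd.Series(protein_ids, index=protein_ids),
    )
    truth = GroundTruth(
        differential_flags=pd.Series(diff, index=protein_ids),
        true_log2fc=pd.Series(true_log2fc, index=protein_ids),
    )
    return matrix, truth


def apply_mnar_missingness(
    matrix: IntensityMatrix, config: SyntheticProteomeConfig, seed: int | None = None
) -> IntensityMatrix:
    """Censor entries independently with the logistic MNAR probability.

    Uses ``config.seed + 1`` by default so the dropout pattern is decoupled
    from the intensity draw but still fully determined by the config.
    """
    if matrix.missing_mask().to_numpy().any():
        raise ValueError("apply_mnar_missingness expects a complete matrix")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    vals = matrix.values.to_numpy(dtype=float)
    p = mnar_missing_probability(vals, config)
    drop = rng.random(vals.shape) < p
    censored = vals.copy()
    censored[drop] = np.nan
    return matrix.with_values(
        pd.DataFrame(censored, index=matrix.values.index, columns=matrix.values.columns)
    )


def generate_channel_table(
    stoichiometry: "pd.Series | dict[str, int]",
    true_copy_numbers: "pd.Series | dict[str, float]",
    anchor: str = "Hcn4",
    anchor_count: int = 6255,
    anchor_ibaq: float = 1.0e7,
    cv: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Build a per-replicate iBAQ table from known channel copy numbers.

    iBAQ is proportional to protein molar abundance, i.e. copies-per-cell x
    subunits-per-channel. Each replicate value is
    ``(true_count * s / anchor_count) * anchor_ibaq * (1 + eps)`` with
    multiplicative Gaussian noise ``eps ~ Normal(0, cv^2)`` (intensities are
    log-normal in practice, so noise acts on the linear scale). Feeding the
    table to the copy-number estimator recovers the true counts — exactly at
    ``cv=0``.
    """
    stoich = pd.Series(stoichiometry, dtype=float)
    truth_counts = pd.Series(true_copy_numbers, dtype=float)
    if anchor not in stoich.index:
        raise ValueError(f"anchor protein {anchor!r} missing from stoichiometry table")
    if int(stoich[anchor]) != 4:
        raise ValueError(f"anchor {anchor!r} must be a tetramer (4 subunits per channel)")
    truth_counts = truth_counts.copy()
    truth_counts[anchor] = float(anchor_count)

    rng = np.random.default_rng(seed)
    cols = [f"iBAQ rep{j + 1}" for j in range(n_replicates)]
    s_anchor = stoich[anchor]
    rows = {}
    for prot in truth_counts.index:
        if prot not in stoich.index:
            raise ValueError(f"protein {prot!r} missing from stoichiometry table")
        base = (truth_counts[prot] * stoich[prot] / (anchor_count * s_anchor)) * anchor_ibaq
        noise = rng.normal(0.0, cv, size=n_replicates) if cv > 0 else np.zeros(n_replicates)
        rows[prot] = base * (1.0 + noise)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    table.index.name = "protein"
    truth = GroundTruth(
        differential_flags=pd.Series(False, index=table.index),
        true_log2fc=pd.Series(0.0, index=table.index),
        true_copy_numbers=truth_counts,
    )
    return table, truth
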