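"""Absolute ion-channel copy numbers per sinus-node myocyte from iBAQ.

iBAQ intensity is a proxy for molar protein abundance. Dividing each
channel protein's iBAQ by the number of subunits that make one functional
channel gives a quantity proportional to channels per cell; anchoring the
ratios to an independent estimate of HCN4 channels per myocyte (6255, from
Markov-chain single-channel modelling of the funny current) converts them
into absolute counts:

    N_X = N_anchor * (iBAQ_X / s_X) / (iBAQ_anchor / s_anchor)

Counts are computed per replicate with the replicate-matched anchor
intensity, then summarized as mean with SD (SEM optional).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ANCHOR_PROTEIN = "Hcn4"
ANCHOR_SUBUNITS = 4
ANCHOR_COUNT = 6255


@dataclass
class StoichiometryTable:
    """Protein -> subunits-per-functional-channel mapping.

    The anchor (HCN4, a tetramer) must be present with s = 4. Defaults
    shipped with the package follow standard channel biochemistry: tetramers
    for HCN, Kir, Kv and Ryr families; dimers for two-pore K+ channels;
    monomers for Cav alpha subunits, Serca2 and Ncx1. Only HCN4 = 4 and
    Cav1.2 = 1 are fixed by the analysis convention; everything is
    user-overridable.
    """

    subunits: pd.Series

    def __post_init__(self) -> None:
        self.subunits = pd.Series(self.subunits, dtype=int)
        if (self.subunits < 1).any():
            bad = list(self.subunits.index[self.subunits < 1])
            raise ValueError(f"subunit counts must be >= 1: {bad}")
        if ANCHOR_PROTEIN not in self.subunits.index:
            raise ValueError(f"anchor protein {ANCHOR_PROTEIN!r} missing")
        if int(self.subunits[ANCHOR_PROTEIN]) != ANCHOR_SUBUNITS:
            raise ValueError(
                f"anchor {ANCHOR_PROTEIN!r} must have {ANCHOR_SUBUNITS} subunits"
            )

    def __getitem__(self, protein: str) -> int:
        return int(self.subunits[protein])

    def __contains__(self, protein: str) -> bool:
        return protein in self.subunits.index

    @classmethod
    def default(cls) -> "StoichiometryTable":
        """Load the stoichiometry table shipped with the package."""
        path = resources.files("sinode.data") / "stoichiometry.tsv"
        with resources.as_file(path) as p:
            df = pd.read_csv(p, sep="\t")
        return cls(pd.Series(df["subunits"].to_numpy(), index=df["protein"]))

    @classmethod
    def from_tsv(cls, path) -> "StoichiometryTable":
        df = pd.read_csv(path, sep="\t")
        return cls(pd.Series(df["subunits"].to_numpy(), index=df["protein"]))


@dataclass
class CopyNumberEstimate:
    """Per-channel absolute copy-number estimate across replicates."""

    protein: str
    per_replicate_counts: np.ndarray
    mean_count: float
    dispersion: float
    dispersion_kind: str = "sd"
    anchor_count: int = ANCHOR_COUNT

    def __post_init__(self) -> None:
        self.per_replicate_counts = np.asarray(self.per_replicate_counts, dtype=float)
        if (self.per_replicate_counts < 0).any():
            raise ValueError("copy numbers must be >= 0")


def channels_per_cell(
    ibaq_x: float,
    s_x: int,
    ibaq_anchor: float,
    s_anchor: int = ANCHOR_SUBUNITS,
    n_anchor: int = ANCHOR_COUNT,
) -> float:
    """Copy number of channel X per cell, anchored to HCN4.

    Scale-invariant in the iBAQ units: only the ratio to the anchor enters.
    """
    if ibaq_x <= 0 or ibaq_anchor <= 0:
        raise ValueError(
            "non-positive iBAQ intensity: a missing channel must be reported "
            "as absent, not divided"
        )
    if s_x < 1 or s_anchor < 1:
        raise ValueError("subunit counts must be >= 1")
    return n_anchor * (ibaq_x / s_x) / (ibaq_anchor / s_anchor)


def summarize_replicates(
    ibaq_table: pd.DataFrame,
    stoichiometry: StoichiometryTable,
    n_anchor: int = ANCHOR_COUNT,
    dispersion: str = "sd",
) -> pd.DataFrame:
    """Replicate-matched copy numbers for every protein in the table.

    For each replicate column, every protein's count is computed against
    that replicate's anchor intensity; mean and dispersion are then taken
    across replicates (``dispersion="sd"`` default, ``"sem"`` optional).
    Replicates in which the anchor is missing are excluded with a warning.

    Returns a DataFrame indexed by protein with one ``count <rep>`` column
    per usable replicate plus ``mean_count`` and ``dispersion``.
    """
    if dispersion not in ("sd", "sem"):
        raise ValueError("dispersion must be 'sd' or 'sem'")
    if ANCHOR_PROTEIN not in ibaq_table.index:
        raise ValueError(f"anchor protein {ANCHOR_PROTEIN!r} not quantified")
    anchor_row = ibaq_table.loc[ANCHOR_PROTEIN]
    usable = []
    for col in ibaq_table.columns:
        a = anchor_row[col]
        if pd.isna(a) or a <= 0:
            logger.warning("anchor %s missing in replicate %s; excluded", ANCHOR_PROTEIN, col)
            continue
        usable.append(col)
    if len(usable) < 2:
        raise ValueError("need the anchor quantified in at least 2 replicates")

    s_anchor = stoichiometry[ANCHOR_PROTEIN]
    rows = {}
    for prot in ibaq_table.index:
        if prot not in stoichiometry:
            logger.warning("protein %s absent from stoichiometry table; skipped", prot)
            continue
        s_x = stoichiometry[prot]
        counts = []
        for col in usable:
            v = ibaq_table.loc[prot, col]
            if pd.isna(v) or v <= 0:
                counts.append(np.nan)
            else:
                counts.append(
                    channels_per_cell(v, s_x, anchor_row[col], s_anchor, n_anchor)
                )
        rows[prot] = counts
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"count {c}" for c in usable]
    )
    out.index.name = "protein"
    out["mean_count"] = out.mean(axis=1)
    sd = out[[f"count {c}" for c in usable]].std(axis=1, ddof=1)
    if dispersion == "sem":
        nrep = out[[f"count {c}" for c in usable]].notna().sum(axis=1)
        sd = sd / np.sqrt(nrep)
    out["dispersion"] = sd
    out.attrs["dispersion_kind"] = dispersion
    out.attrs["anchor_count"] = n_anchor
    return out
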