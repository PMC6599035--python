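"""In-memory containers shared across the pipeline.

The central object is :class:`IntensityMatrix`, a proteins x samples table of
log2 intensities with per-sample group labels (sinus node ``SN`` vs right
atrium ``RA``) and the per-protein annotation MaxQuant-style exports carry
(peptide counts, reverse/contaminant flags, isoform groups). Missing values
are ``NaN``; MaxQuant writes them as zeros and the readers translate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

GROUP_SN = "SN"
GROUP_RA = "RA"


@dataclass
class IntensityMatrix:
    """Proteins x samples log2-intensity table with annotations.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by protein id, one column per sample, log2 intensities
        with NaN for missing. Values must be finite where present.
    group_labels : pandas.Series
        Sample -> group (``"SN"`` or ``"RA"``), indexed like the columns.
    peptide_counts : pandas.Series, optional
        Per-protein identified-peptide counts.
    reverse_flag, contaminant_flag : pandas.Series, optional
        Per-protein booleans marking decoy / contaminant identifications.
    isoform_group : pandas.Series, optional
        Per-protein identifier naming the canonical gene-level group the
        protein isoform belongs to.
    """

    values: pd.DataFrame
    group_labels: pd.Series
    peptide_counts: pd.Series | None = None
    reverse_flag: pd.Series | None = None
    contaminant_flag: pd.Series | None = None
    isoform_group: pd.Series | None = None
    scale: str = "log2"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.group_labels = pd.Series(self.group_labels)
        missing_labels = [c for c in self.values.columns if c not in self.group_labels.index]
        if missing_labels:
            raise ValueError(f"samples without group label: {missing_labels}")
        self.group_labels = self.group_labels.loc[list(self.values.columns)]
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValueError("intensity values must be finite where present")
        if self.scale not in ("log2", "linear"):
            raise ValueError(
                "scale must be declared as 'log2' or 'linear'; "
                "automatic magnitude-based detection is deliberately unsupported"
            )
        for name in ("peptide_counts", "reverse_flag", "contaminant_flag", "isoform_group"):
            s = getattr(self, name)
            if s is not None:
                setattr(self, name, pd.Series(s).loc[self.values.index])

    # -- basic introspection -------------------------------------------------

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s, g in self.group_labels.items() if g == group]

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.group_labels:
            if g not in seen:
                seen.append(g)
        return seen

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def subset(self, protein_ids: Sequence) -> "IntensityMatrix":
        """Row-subset preserving all annotations."""
        idx = pd.Index(protein_ids)
        return replace(
            self,
            values=self.values.loc[idx],
            peptide_counts=None if self.peptide_counts is None else self.peptide_counts.loc[idx],
            reverse_flag=None if self.reverse_flag is None else self.reverse_flag.loc[idx],
            contaminant_flag=None
            if self.contaminant_flag is None
            else self.contaminant_flag.loc[idx],
            isoform_group=None if self.isoform_group is None else self.isoform_group.loc[idx],
        )

    def with_values(self, values: pd.DataFrame) -> "IntensityMatrix":
        """Same annotations, new value table (index/columns must match)."""
        if not values.index.equals(self.values.index) or not values.columns.equals(
            self.values.columns
        ):
            raise ValueError("replacement values must share index and columns")
        return replace(self, values=values)

    def copy(self) -> "IntensityMatrix":
        return replace(
            self,
            values=self.values.copy(),
            group_labels=self.group_labels.copy(),
            peptide_counts=None if self.peptide_counts is None else self.peptide_counts.copy(),
            reverse_flag=None if self.reverse_flag is None else self.reverse_flag.copy(),
            contaminant_flag=None
            if self.contaminant_flag is None
            else self.contaminant_flag.copy(),
            isoform_group=None if self.isoform_group is None else self.isoform_group.copy(),
        )


@dataclass
class GroundTruth:
    """Known truth attached to synthetic data.

    ``true_log2fc`` is the SN-minus-RA mean shift used in generation;
    non-differential proteins carry exactly zero. ``true_copy_numbers`` is
    populated for synthetic channel tables.
    """

    differential_flags: pd.Series
    true_log2fc: pd.Series
    true_copy_numbers: pd.Series | None = None

    def __post_init__(self) -> None:
        nondiff = ~self.differential_flags.astype(bool)
        if not np.allclose(self.true_log2fc[nondiff], 0.0):
            raise ValueError("non-differential proteins must have true_log2fc == 0")
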