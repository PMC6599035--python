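"""File formats and run manifests.

The protein-table dialect is the MaxQuant ``proteinGroups.txt`` family:
tab-separated, one row per protein group, with ``LFQ intensity <sample>``
and ``iBAQ <sample>`` columns, ``+`` marking reverse/contaminant rows, and
zero standing for "not quantified" (translated to missing on read; the
convention is undocumented in the exports themselves but universal).
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import IntensityMatrix

PROTEIN_ID_COL = "Protein IDs"
PEPTIDES_COL = "Peptides"
REVERSE_COL = "Reverse"
CONTAMINANT_COL = "Potential contaminant"
ISOFORM_COL = "Isoform group"
LFQ_PREFIX = "LFQ intensity "
IBAQ_PREFIX = "iBAQ "


def _infer_group(sample: str) -> str:
    for g in ("SN", "RA"):
        if sample.upper().startswith(g):
            return g
    raise ValueError(
        f"cannot infer group for sample {sample!r}; expected names starting SN/RA "
        "or an explicit group_labels mapping"
    )


def read_protein_table(
    path, group_labels: dict[str, str] | None = None
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Read a MaxQuant-style TSV into an IntensityMatrix plus iBAQ table.

    LFQ intensities are log2-transformed with zeros read as missing; the
    iBAQ table is returned on the linear scale (NaN for missing). Flags use
    the '+' convention. Raises when mandatory columns are absent or sample
    names are duplicated.
    """
    df = pd.read_csv(path, sep="\t", dtype={REVERSE_COL: str, CONTAMINANT_COL: str})
    missing = [c for c in (PROTEIN_ID_COL, PEPTIDES_COL) if c not in df.columns]
    if missing:
        raise ValueError(f"mandatory columns missing from {path}: {missing}")
    lfq_cols = [c for c in df.columns if c.startswith(LFQ_PREFIX)]
    ibaq_cols = [c for c in df.columns if c.startswith(IBAQ_PREFIX) and c != "iBAQ"]
    if not lfq_cols:
        raise ValueError(f"no '{LFQ_PREFIX}<sample>' columns in {path}")
    samples = [c[len(LFQ_PREFIX) :] for c in lfq_cols]
    if len(set(samples)) != len(samples):
        raise ValueError(f"duplicated sample names in {path}: {samples}")

    ids = pd.Index(df[PROTEIN_ID_COL].astype(str), name="protein")
    if ids.duplicated().any():
        raise ValueError(f"duplicated protein ids in {path}")
    lfq = df[lfq_cols].to_numpy(dtype=float)
    lfq[lfq <= 0] = np.nan  # MaxQuant writes 0 for not-quantified
    values = pd.DataFrame(np.log2(lfq), index=ids, columns=samples)

    labels = pd.Series(
        {s: (group_labels[s] if group_labels else _infer_group(s)) for s in samples}
    )
    flags = {}
    for col, attr in ((REVERSE_COL, "reverse_flag"), (CONTAMINANT_COL, "contaminant_flag")):
        if col in df.columns:
            flags[attr] = pd.Series(
                (df[col].fillna("") == "+").to_numpy(), index=ids
            )
    isoform = (
        pd.Series(df[ISOFORM_COL].astype(str).to_numpy(), index=ids)
        if ISOFORM_COL in df.columns
        else None
    )
    matrix = IntensityMatrix(
        values=values,
        group_labels=labels,
        peptide_counts=pd.Series(df[PEPTIDES_COL].to_numpy(dtype=int), index=ids),
        isoform_group=isoform,
        **flags,
    )
    if ibaq_cols:
        ibaq = df[ibaq_cols].to_numpy(dtype=float)
        ibaq[ibaq <= 0] = np.nan
        ibaq_table = pd.DataFrame(
            ibaq, index=ids, columns=[c[len(IBAQ_PREFIX) :] for c in ibaq_cols]
        )
    else:
        ibaq_table = pd.DataFrame(index=ids)
    return matrix, ibaq_table


def write_protein_table(
    path, matrix: IntensityMatrix, ibaq_table: pd.DataFrame | None = None
) -> None:
    """Write the MaxQuant-like dialect (zeros for missing, '+' flags).

    Round-trips losslessly with :func:`read_protein_table` for finite
    values and missingness.
    """
    out = pd.DataFrame({PROTEIN_ID_COL: matrix.protein_ids})
    out[PEPTIDES_COL] = (
        matrix.peptide_counts.to_numpy() if matrix.peptide_counts is not None else 2
    )
    for col, s in (
        (REVERSE_COL, matrix.reverse_flag),
        (CONTAMINANT_COL, matrix.contaminant_flag),
    ):
        out[col] = np.where(s.to_numpy() if s is not None else False, "+", "")
    if matrix.isoform_group is not None:
        out[ISOFORM_COL] = matrix.isoform_group.to_numpy()
    linear = np.exp2(matrix.values.to_numpy(dtype=float))
    linear = np.where(np.isnan(linear), 0.0, linear)
    for j, s in enumerate(matrix.samples):
        out[LFQ_PREFIX + s] = linear[:, j]
    if ibaq_table is not None:
        vals = ibaq_table.to_numpy(dtype=float)
        vals = np.where(np.isnan(vals), 0.0, vals)
        for j, s in enumerate(ibaq_table.columns):
            out[IBAQ_PREFIX + str(s)] = vals[:, j]
    out.to_csv(path, sep="\t", index=False)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written next to every pipeline output."""

    tool: str = "sinode"
    version: str = "0.1.0"
    seed: int | None = None
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # path -> sha256
    outputs: dict = field(default_factory=dict)
    stages_completed: list = field(default_factory=list)
    timestamp: str = ""
    platform: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()
        if not self.platform:
            self.platform = platform.platform()

    def record_input(self, path) -> None:
        self.inputs[str(path)] = sha256_of(path)

    def record_output(self, path) -> None:
        self.outputs[str(path)] = sha256_of(path)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))
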