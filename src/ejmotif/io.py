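"""File-format adapters: FASTA eJM panels, weighting-scheme TSVs,
long-format intensity tables, glycan CSVs and single-channel images."""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif import EjmSequence, MotifModel, PositionWeighting

PANEL_CLASSES = {"A", "B", "?"}


def read_ejm_fasta(path) -> List[Tuple[EjmSequence, Optional[str]]]:
    """Read an eJM panel; headers follow ``>rtk_id|species|class``.

    The class field is "A", "B" or "?" (unknown -> label None).
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.id.split("|")
        rtk_id = fields[0]
        species = fields[1] if len(fields) > 1 else "unknown"
        label = fields[2] if len(fields) > 2 else "?"
        if label not in PANEL_CLASSES:
            raise ValueError(f"bad class field {label!r} in header {rec.id!r}")
        seq = EjmSequence(rtk_id=rtk_id, sequence=str(rec.seq), species=species)
        out.append((seq, None if label == "?" else label))
    return out


def write_ejm_fasta(path, panel) -> None:
    """Write (EjmSequence, label-or-None) pairs as a panel FASTA."""
    records = []
    for seq, label in panel:
        header = f"{seq.rtk_id}|{seq.species}|{label or '?'}"
        records.append(SeqRecord(Seq(seq.sequence), id=header, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_weightings_tsv(path) -> List[PositionWeighting]:
    """One weighting scheme per row, six weight columns (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    first = df.iloc[0]
    if not np.issubdtype(df.dtypes.iloc[0], np.number):
        try:
            [float(x) for x in first]
        except (TypeError, ValueError):
            df = df.iloc[1:].astype(float)
    if df.shape[1] != 6:
        raise ValueError("weighting file must have exactly six columns")
    return [PositionWeighting(tuple(row)) for row in df.astype(float).values]


def model_from_weightings_tsv(path) -> MotifModel:
    return MotifModel(weightings=tuple(read_weightings_tsv(path)))


def read_intensity_tsv(path) -> pd.DataFrame:
    """Long-format LFQ table: protein_id, experiment, sample, fraction,
    condition, intensity."""
    df = pd.read_csv(path, sep="\t")
    df["intensity"] = df["intensity"].astype(float)
    return df


def read_glycan_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_image(path) -> np.ndarray:
    """Single-channel 2-D image from TIFF or PNG, promoted to float."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        img = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        img = iio.imread(str(path))
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    return img
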