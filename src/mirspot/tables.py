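"""Tabular I/O for spotted-array experiments.

All files are plain tab-separated text.  Spot tables carry one row per
printed spot (array, probe, replicate, foreground/background medians and a
quality flag), mirroring what a GenePix-style extraction exports.  Intensity
matrices are probes x arrays with the empty string as the missing marker
(the Cluster 3.0 convention).  Hierarchical-clustering results are written
in the Cluster 3.0 / Java TreeView CDT + GTR text formats.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError

FLAG_OK = "ok"
FLAG_POOR = "poor_quality"

PROBE_CLASSES = (
    "human",
    "negative_control",
    "spike",
    "specificity_pm",
    "specificity_mismatch",
    "specificity_shuffled",
    "blank",
)

#: Matrix processing stages in their only legal order.
STAGES = ("raw", "log2", "normalized", "averaged", "detected")

SPOT_COLUMNS = ["array_id", "probe_id", "replicate_index", "fg_median", "bg_median", "flag"]
ANNOTATION_COLUMNS = ["probe_id", "display_name", "probe_class", "species"]
DESIGN_COLUMNS = ["array_id", "group"]


def flag_from_genepix(value: int) -> str:
    """Map a GenePix numeric flag to the two-state quality flag.

    GenePix marks bad/absent spots with negative flag values; zero and
    positive values are usable spots.
    """
    return FLAG_POOR if value < 0 else FLAG_OK


def read_spot_table(source) -> pd.DataFrame:
    """Read a spot-level TSV into a DataFrame with the canonical columns.

    Parameters
    ----------
    source : path or readable text stream
        Tab-separated file with a header containing at least the columns
        ``array_id, probe_id, replicate_index, fg_median, bg_median, flag``.
        Unknown extra columns are ignored.  Input row order is preserved.

    Raises
    ------
    FormatError
        If a required column is missing (named in the message) or an
        intensity value is non-numeric (line number in the message).
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    for col in SPOT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"spot table is missing required column {col!r}")
    df = df[SPOT_COLUMNS].copy()
    for col in ("replicate_index", "fg_median", "bg_median"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise FormatError(f"non-numeric value in column {col!r} at line {line}")
        df[col] = converted
    df["replicate_index"] = df["replicate_index"].astype(int)
    if not df["flag"].isin([FLAG_OK, FLAG_POOR]).all():
        bad = df.loc[~df["flag"].isin([FLAG_OK, FLAG_POOR]), "flag"].iloc[0]
        raise FormatError(f"unknown quality flag {bad!r} (expected ok/poor_quality)")
    if not np.isfinite(df[["fg_median", "bg_median"]].to_numpy(float)).all():
        raise FormatError("fg_median/bg_median must be finite")
    if not df["replicate_index"].between(1, 3).all():
        raise FormatError("replicate_index must be within 1..3")
    return df.reset_index(drop=True)


def write_spot_table(df: pd.DataFrame, path) -> None:
    df[SPOT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_probe_annotation(source) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", dtype=str)
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"probe annotation is missing required column {col!r}")
    df = df[ANNOTATION_COLUMNS].copy()
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise FormatError(f"duplicate probe_id {dup!r} in annotation")
    unknown = set(df["probe_class"]) - set(PROBE_CLASSES)
    if unknown:
        raise FormatError(f"unknown probe_class values: {sorted(unknown)}")
    return df.reset_index(drop=True)


def write_probe_annotation(df: pd.DataFrame, path) -> None:
    df[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_design(source) -> pd.Series:
    """Read the array -> group assignment; returns a Series indexed by array_id."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    for col in DESIGN_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"design table is missing required column {col!r}")
    if df["array_id"].duplicated().any():
        raise FormatError("design assigns an array to more than one group")
    return df.set_index("array_id")["group"]


def write_design(design: pd.Series, path) -> None:
    design.rename("group").rename_axis("array_id").reset_index().to_csv(path, sep="\t", index=False)


@dataclass
class IntensityMatrix:
    """Probes x arrays matrix of intensities with a processing-stage label.

    ``data`` is a float DataFrame (rows: probe ids, columns: array ids) with
    NaN as the in-memory missing marker; on disk missing cells are empty
    strings.  ``stage`` advances only along ``raw -> log2 -> normalized ->
    averaged -> detected``.
    """

    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ConsistencyError(f"unknown stage {self.stage!r}")
        vals = self.data.to_numpy(float)
        if np.isneginf(vals).any() or np.isposinf(vals).any():
            raise ConsistencyError("intensity matrix contains infinities")

    def advanced(self, data: pd.DataFrame, stage: str) -> "IntensityMatrix":
        """Return a new matrix at a later stage, enforcing the stage order."""
        if STAGES.index(stage) <= STAGES.index(self.stage):
            raise ConsistencyError(f"illegal stage transition {self.stage} -> {stage}")
        return IntensityMatrix(data, stage)

    @property
    def arrays(self):
        return list(self.data.columns)

    @property
    def probes(self):
        return list(self.data.index)


def write_intensity_matrix(matrix: IntensityMatrix, path) -> None:
    matrix.data.rename_axis("probe_id").to_csv(path, sep="\t", na_rep="")


def read_intensity_matrix(source, stage: str) -> IntensityMatrix:
    df = pd.read_csv(source, sep="\t", index_col="probe_id")
    return IntensityMatrix(df.astype(float), stage)


# ---------------------------------------------------------------------------
# Cluster 3.0 tree formats
# ---------------------------------------------------------------------------

def _gene_id(i: int) -> str:
    return f"GENE{i}X"


def _node_id(i: int) -> str:
    return f"NODE{i}X"


def write_gtr(tree, path) -> None:
    """Write the merge list as a GTR (gene tree) file.

    One line per join: ``NODEkX  childA  childB  similarity`` with children
    given as GENEiX / NODEjX identifiers and similarities in merge order
    (non-increasing for average linkage).
    """
    n = len(tree.leaf_order)
    lines = []
    for rank, (node, left, right, sim) in enumerate(tree.merges, start=1):
        ids = []
        for child in (left, right):
            ids.append(_gene_id(child) if child < n else _node_id(child - n + 1))
        lines.append(f"{_node_id(rank)}\t{ids[0]}\t{ids[1]}\t{sim:.6f}")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def read_gtr(source):
    """Parse a GTR file back into (merges, n_leaves).

    Returns the merge list as ``(node_index, left, right, similarity)`` using
    the same integer labelling as the in-memory tree (leaves ``0..n-1``,
    internal nodes ``n..2n-2``).
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    merges = []
    leaf_ids = set()
    for line in text.strip().splitlines():
        node, a, b, sim = line.split("\t")
        idx = int(node[4:-1])
        children = []
        for tok in (a, b):
            if tok.startswith("GENE"):
                leaf = int(tok[4:-1])
                leaf_ids.add(leaf)
                children.append(("leaf", leaf))
            else:
                children.append(("node", int(tok[4:-1])))
        merges.append((idx, children, float(sim)))
    n = max(leaf_ids) + 1 if leaf_ids else 0
    out = []
    for idx, children, sim in merges:
        resolved = [c if kind == "leaf" else n + c - 1 for kind, c in children]
        out.append((n + idx - 1, resolved[0], resolved[1], sim))
    return out, n


def write_cdt(tree, matrix: IntensityMatrix, path) -> None:
    """Write the clustered data table (CDT) with rows in tree leaf order."""
    probes = matrix.probes
    if set(tree.leaf_order) != set(range(len(probes))):
        raise ConsistencyError("tree leaves do not match matrix rows")
    buf = _io.StringIO()
    arrays = matrix.arrays
    buf.write("GID\tUNIQID\tNAME\tGWEIGHT\t" + "\t".join(arrays) + "\n")
    buf.write("EWEIGHT\t\t\t" + "\t" + "\t".join(["1"] * len(arrays)) + "\n")
    for leaf in tree.leaf_order:
        probe = probes[leaf]
        row = matrix.data.iloc[leaf]
        cells = ["" if pd.isna(v) else f"{v:.6g}" for v in row]
        buf.write(f"{_gene_id(leaf)}\t{probe}\t{probe}\t1\t" + "\t".join(cells) + "\n")
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def write_cdt_gtr(tree, matrix: IntensityMatrix, cdt_path, gtr_path) -> None:
    """Emit the Cluster 3.0 output pair for a clustered matrix."""
    write_cdt(tree, matrix, cdt_path)
    write_gtr(tree, gtr_path)
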