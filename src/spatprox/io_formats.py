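"""Readers and writers for every external format the pipeline touches.

On-disk conventions follow the 10x Visium ecosystem: counts as a
MatrixMarket coordinate-integer triplet plus ``features.tsv`` /
``barcodes.tsv`` sidecars, spot coordinates as the six-column
``tissue_positions`` CSV (headered or headerless dialect), deconvolution
scores / ligand-receptor catalogues / sample sheets as TSV, and cell-type
signatures as GMT. Readers validate and reject malformed input; every
writer round-trips through its paired reader.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError

GROUPS = ("primary", "recurrent")

#: Visium tissue_positions column order (x = pxl_col, y = pxl_row).
POSITIONS_COLUMNS = (
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
)


@dataclass
class SpatialSample:
    """One tissue section: counts, spot coordinates and its cohort group.

    Attributes
    ----------
    sample_id : str
        Unique sample identifier.
    group : str
        Cohort arm, ``"primary"`` or ``"recurrent"``.
    counts : scipy.sparse.csr_matrix
        Non-negative integer gene x spot matrix.
    gene_ids, spot_ids : list of str
        Row / column identifiers; spot ids are unique.
    coords : numpy.ndarray
        ``(n_spots, 2)`` array of (x, y) positions.
    """

    sample_id: str
    group: str
    counts: sp.csr_matrix
    gene_ids: list[str]
    spot_ids: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        self.validate()

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise FormatError(
                f"sample {self.sample_id!r}: group {self.group!r} "
                f"not in {GROUPS}"
            )
        ng, ns = self.counts.shape
        if ng != len(self.gene_ids):
            raise FormatError(
                f"sample {self.sample_id!r}: {ng} matrix rows but "
                f"{len(self.gene_ids)} gene ids"
            )
        if ns != len(self.spot_ids):
            raise FormatError(
                f"sample {self.sample_id!r}: {ns} matrix columns but "
                f"{len(self.spot_ids)} spot ids"
            )
        if len(set(self.spot_ids)) != len(self.spot_ids):
            raise FormatError(f"sample {self.sample_id!r}: duplicate spot ids")
        if self.coords.shape != (ns, 2):
            raise FormatError(
                f"sample {self.sample_id!r}: coords shape {self.coords.shape} "
                f"!= ({ns}, 2)"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError(f"sample {self.sample_id!r}: negative counts")


def log_normalize(sample: SpatialSample, target_sum: float = 1e4) -> sp.csr_matrix:
    """Library-size normalise to ``target_sum`` counts per spot, then log1p.

    Returns a CSR matrix of the same shape as ``sample.counts``. Spots with
    zero total counts are left all-zero.
    """
    X = sample.counts.astype(float).tocsc()
    totals = np.asarray(X.sum(axis=0)).ravel()
    scale = np.divide(
        target_sum, totals, out=np.zeros_like(totals), where=totals > 0
    )
    X = X @ sp.diags(scale)
    X.data = np.log1p(X.data)
    return X.tocsr()


# ---------------------------------------------------------------------------
# counts triplet + positions


def read_sample(
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    positions_path: str | Path,
    sample_id: str,
    group: str,
) -> SpatialSample:
    """Read one sample from a 10x-style triplet plus a positions CSV.

    The matrix orientation is auto-detected by matching an axis length to
    the barcode count (ambiguous square matrices are rejected). Spots whose
    barcode is absent from the positions file raise :class:`FormatError`;
    positions rows with ``in_tissue == 0`` are dropped from the sample.
    """
    mtx_path = Path(mtx_path)
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # pragma: no cover - scipy message varies
        raise FormatError(f"{mtx_path}: not a valid MatrixMarket file: {exc}")
    mat = sp.coo_matrix(mat)
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError(f"{mtx_path}: non-integer values in count matrix")
    if mat.nnz and mat.data.min() < 0:
        raise FormatError(f"{mtx_path}: negative values in count matrix")
    mat = sp.csr_matrix(mat, dtype=np.int64)

    gene_ids = _read_id_column(features_path)
    barcodes = _read_id_column(barcodes_path)

    if mat.shape == (len(gene_ids), len(barcodes)):
        if len(gene_ids) == len(barcodes):
            raise FormatError(
                f"{mtx_path}: square matrix, orientation ambiguous"
            )
    elif mat.shape == (len(barcodes), len(gene_ids)):
        mat = sp.csr_matrix(mat.T)
    else:
        raise FormatError(
            f"{mtx_path}: shape {mat.shape} matches neither "
            f"(genes={len(gene_ids)}, spots={len(barcodes)}) orientation"
        )

    pos = read_positions(positions_path)
    missing = [bc for bc in barcodes if bc not in pos.index]
    if missing:
        raise FormatError(
            f"{positions_path}: barcodes missing from positions: "
            + ", ".join(missing[:10])
            + ("..." if len(missing) > 10 else "")
        )
    pos = pos.loc[barcodes]
    keep = pos["in_tissue"].to_numpy() != 0
    mat = sp.csr_matrix(mat[:, keep])
    spot_ids = [bc for bc, k in zip(barcodes, keep) if k]
    coords = pos.loc[keep, ["x", "y"]].to_numpy(dtype=float)
    return SpatialSample(sample_id, group, mat, gene_ids, spot_ids, coords)


def read_positions(path: str | Path) -> pd.DataFrame:
    """Read a Visium positions CSV (headered or headerless dialect).

    Returns a frame indexed by barcode with ``in_tissue``, ``x``, ``y``
    columns (x = pxl_col, y = pxl_row).
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    header = 0 if first.lower().startswith("barcode") else None
    pos = pd.read_csv(path, header=header)
    if pos.shape[1] != len(POSITIONS_COLUMNS):
        raise FormatError(
            f"{path}: expected {len(POSITIONS_COLUMNS)} columns, "
            f"got {pos.shape[1]}"
        )
    pos.columns = list(POSITIONS_COLUMNS)
    if pos["barcode"].duplicated().any():
        raise FormatError(f"{path}: duplicate barcodes in positions")
    pos = pos.set_index("barcode")
    pos["x"] = pos["pxl_col_in_fullres"].astype(float)
    pos["y"] = pos["pxl_row_in_fullres"].astype(float)
    return pos


def write_sample(sample: SpatialSample, out_dir: str | Path) -> dict[str, Path]:
    """Write a sample as matrix.mtx / features.tsv / barcodes.tsv / positions.csv.

    Returns the mapping of logical name to path; ``read_sample`` on these
    paths reconstructs an equal sample.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out_dir / "matrix.mtx",
        "features": out_dir / "features.tsv",
        "barcodes": out_dir / "barcodes.tsv",
        "positions": out_dir / "positions.csv",
    }
    scipy.io.mmwrite(
        str(paths["mtx"]), sp.coo_matrix(sample.counts), field="integer"
    )
    paths["features"].write_text(
        "".join(f"{g}\n" for g in sample.gene_ids), encoding="utf-8"
    )
    paths["barcodes"].write_text(
        "".join(f"{b}\n" for b in sample.spot_ids), encoding="utf-8"
    )
    pos = pd.DataFrame(
        {
            "barcode": sample.spot_ids,
            "in_tissue": 1,
            "array_row": 0,
            "array_col": 0,
            "pxl_row_in_fullres": sample.coords[:, 1],
            "pxl_col_in_fullres": sample.coords[:, 0],
        }
    )
    pos.to_csv(paths["positions"], index=False)
    return paths


def _read_id_column(path: str | Path) -> list[str]:
    path = Path(path)
    ids = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[0])
    if not ids:
        raise FormatError(f"{path}: empty id file")
    return ids


# ---------------------------------------------------------------------------
# deconvolution scores


def read_deconv(path: str | Path) -> pd.DataFrame:
    """Read a spot x cell-type prediction-score TSV (barcode index column).

    Scores must lie in [0, 1] and row sums must not exceed 1; excesses
    (per value or per row sum) smaller than 1e-6 are clipped back with a
    warning, anything larger — or any negative value — is a
    :class:`FormatError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"{path}: empty deconvolution table")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric score: {exc}")
    vals = df.to_numpy()
    if (vals < 0).any():
        raise FormatError(f"{path}: negative prediction scores")
    excess = max(vals.max() - 1.0, vals.sum(axis=1).max() - 1.0)
    if excess > 1e-6:
        raise FormatError(
            f"{path}: prediction scores exceed 1 (by {excess:.3g}, beyond "
            "the 1e-6 tolerance)"
        )
    if excess > 0:
        warnings.warn(
            f"{path}: clipping score rows exceeding 1 by at most {excess:.2e}",
            stacklevel=2,
        )
        df = df.clip(upper=1.0)
        sums = df.sum(axis=1)
        df.loc[sums > 1.0] = df.loc[sums > 1.0].div(sums[sums > 1.0], axis=0)
    return df


def write_deconv(scores: pd.DataFrame, path: str | Path) -> Path:
    # 9 significant digits keep re-read row sums within the 1e-6 tolerance
    path = Path(path)
    scores.to_csv(path, sep="\t", index_label="barcode", float_format="%.9g")
    return path


# ---------------------------------------------------------------------------
# GMT signatures


def read_signatures(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered ``{set name: gene list}`` mapping.

    GMT: one set per line, tab separated ``name, description, gene, ...``.
    Duplicate genes within a set are dropped (first occurrence kept);
    empty sets are rejected.
    """
    path = Path(path)
    sigs: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description "
                    "and at least one gene"
                )
            name, genes = parts[0], [g for g in parts[2:] if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: empty gene set {name!r}")
            if name in sigs:
                raise FormatError(f"{path}:{lineno}: duplicate set {name!r}")
            sigs[name] = list(dict.fromkeys(genes))
    if not sigs:
        raise FormatError(f"{path}: no gene sets")
    return sigs


def write_signatures(sigs: Mapping[str, Sequence[str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sigs.items():
            fh.write("\t".join([name, "NA", *genes]) + "\n")
    return path


# ---------------------------------------------------------------------------
# ligand-receptor catalogue


def read_lr(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column (ligand, receptor) TSV with a header row."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: ligand-receptor TSV needs two columns")
    pairs = []
    seen = set()
    for lig, rec in df.iloc[:, :2].itertuples(index=False):
        if not isinstance(lig, str) or not isinstance(rec, str) or not lig or not rec:
            raise FormatError(f"{path}: empty ligand or receptor name")
        if (lig, rec) in seen:
            raise FormatError(f"{path}: duplicate pair ({lig}, {rec})")
        seen.add((lig, rec))
        pairs.append((lig, rec))
    if not pairs:
        raise FormatError(f"{path}: empty catalogue")
    return pairs


def write_lr(pairs: Iterable[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(pairs, columns=["ligand", "receptor"]).to_csv(
        path, sep="\t", index=False
    )
    return path


# ---------------------------------------------------------------------------
# sample sheet and generic result tables


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV with ``sample_id`` and ``group`` columns."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    bad = sorted(set(df["group"]) - set(GROUPS))
    if bad:
        raise FormatError(f"{path}: unknown group labels {bad}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    return df[["sample_id", "group"]].reset_index(drop=True)


def write_table(rows: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table as tab-separated UTF-8.

    Column order is the frame's order; floats are rendered with six
    significant digits, which the paired ``read_table`` recovers exactly.
    """
    path = Path(path)
    rows.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
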