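"""Readers and writers for guide libraries, barcode lists, count matrices and call tables.

All tables are tab-delimited with a header row. The cell x guide UMI count
matrix is exchanged as a MatrixMarket triplet directory (``matrix.mtx`` +
``barcodes.tsv`` + ``features.tsv``), the layout emitted by the common
single-cell pipelines: rows of the on-disk matrix are guides (features),
columns are cell barcodes. In memory the matrix is cells x guides and
0-based; the 1-based on-disk convention is confined to this module.
"""

from __future__ import annotations

import gzip

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "GuideLibrary",
    "BarcodeList",
    "GuideCountMatrix",
    "read_guide_library",
    "read_barcode_list",
    "read_count_matrix",
    "write_count_matrix",
    "write_calls",
    "write_assignments",
]

_DNA = frozenset("ACGT")

@dataclass(frozen=True)
class GuideLibrary:
    """Table of guides: protospacer sequences, target genes, vector grouping.

    Each dual-guide lentiviral vector expresses one or two protospacers
    against a single target, so ``vector_id`` groups at most two guides.
    """

    table: pd.DataFrame  # columns: guide_id, protospacer, target, vector_id

    def __post_init__(self) -> None:
        t = self.table
        required = ["guide_id", "protospacer", "target", "vector_id"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValueError(f"guide library missing columns: {missing}")
        for col in required:
            if t[col].isna().any() or (t[col].astype(str).str.len() == 0).any():
                raise ValueError(f"guide library has empty values in column {col!r}")
        dup = t["guide_id"][t["guide_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate guide_id: {dup.iloc[0]!r}")
        dup = t["protospacer"][t["protospacer"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate protospacer: {dup.iloc[0]!r}")
        for i, ps in enumerate(t["protospacer"]):
            bad = set(ps) - _DNA
            if bad:
                raise ValueError(
                    f"protospacer {ps!r} (line {i + 2}) has non-ACGT character(s) {sorted(bad)}"
                )
            if not 18 <= len(ps) <= 21:
                raise ValueError(
                    f"protospacer {ps!r} (line {i + 2}) length {len(ps)} outside 18-21 nt"
                )
        counts = t.groupby("vector_id")["guide_id"].count()
        if (counts > 2).any():
            off = counts[counts > 2].index[0]
            raise ValueError(f"vector_id {off!r} groups more than 2 guides (dual-guide design)")

    @property
    def guide_ids(self) -> list[str]:
        return list(self.table["guide_id"])

    @property
    def n_guides(self) -> int:
        return len(self.table)

    @property
    def n_vectors(self) -> int:
        return self.table["vector_id"].nunique()

    def target_of(self, guide_id: str) -> str:
        row = self.table.loc[self.table["guide_id"] == guide_id, "target"]
        if row.empty:
            raise KeyError(f"unknown guide_id {guide_id!r}")
        return str(row.iloc[0])

    def guides_of_vector(self, vector_id: str) -> list[str]:
        return list(self.table.loc[self.table["vector_id"] == vector_id, "guide_id"])

    @property
    def vector_ids(self) -> list[str]:
        # first-appearance order
        return list(dict.fromkeys(self.table["vector_id"]))

    def protospacer_map(self) -> dict[str, str]:
        """protospacer sequence -> guide_id."""
        return dict(zip(self.table["protospacer"], self.table["guide_id"]))

@dataclass(frozen=True)
class BarcodeList:
    """Ordered cell-barcode whitelist with an optional captured->canonical translation.

    On the 10x Multiome platform the barcode read of the guide library is in
    ATAC-barcode space while cell calls are usually reported in GEX space;
    the translation map bridges the two. When absent, captured barcodes are
    matched as-is.
    """

    barcodes: tuple[str, ...]
    translation: dict[str, str] | None = None
    _index: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        if self.barcodes:
            L = len(self.barcodes[0])
            bad = [b for b in self.barcodes if len(b) != L]
            if bad:
                raise ValueError(
                    f"mixed barcode lengths: expected {L}, found {len(bad[0])} ({bad[0]!r})"
                )
        if self.translation is not None:
            canonical = set(self.barcodes)
            for v in self.translation.values():
                if v not in canonical:
                    raise ValueError(f"translation target {v!r} not in canonical barcode list")
        object.__setattr__(self, "_index", {b: i for i, b in enumerate(self.barcodes)})

    def __len__(self) -> int:
        return len(self.barcodes)

    def __contains__(self, bc: str) -> bool:
        return self.lookup(bc) is not None

    @property
    def barcode_length(self) -> int:
        if not self.barcodes:
            raise ValueError("empty barcode list has no length")
        return len(self.barcodes[0])

    def lookup(self, bc: str) -> str | None:
        """Translate (if a map is loaded) then check list membership."""
        if self.translation is not None:
            bc = self.translation.get(bc, bc)
        return bc if bc in self._index else None

@dataclass
class GuideCountMatrix:
    """Sparse nonnegative-integer cells x guides UMI count matrix."""

    matrix: sp.csr_matrix  # shape (n_cells, n_guides)
    barcodes: list[str]
    guide_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix, dtype=np.int64)
        if self.matrix.shape != (len(self.barcodes), len(self.guide_ids)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match axes "
                f"({len(self.barcodes)} cells, {len(self.guide_ids)} guides)"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate cell barcodes on matrix axis")
        if len(set(self.guide_ids)) != len(self.guide_ids):
            raise ValueError("duplicate guide_ids on matrix axis")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("negative UMI count in matrix")

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def n_guides(self) -> int:
        return len(self.guide_ids)

    def guide_counts(self, guide_id: str) -> np.ndarray:
        """Dense per-cell count vector for one guide."""
        j = self.guide_ids.index(guide_id)
        return np.asarray(self.matrix[:, j].todense()).ravel()

    def total_per_cell(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GuideCountMatrix):
            return NotImplemented
        return (
            self.barcodes == other.barcodes
            and self.guide_ids == other.guide_ids
            and (self.matrix != other.matrix).nnz == 0
        )

def _open_text(path: str | os.PathLike):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")

def read_guide_library(path: str | os.PathLike) -> GuideLibrary:
    """Read a tab-delimited guide library with columns guide_id, protospacer, target, vector_id.

    Protospacers are uppercased before validation.
    """
    with _open_text(path) as fh:
        table = pd.read_csv(fh, sep="\t", dtype=str)
    table["protospacer"] = table["protospacer"].astype(str).str.upper()
    return GuideLibrary(table.reset_index(drop=True))

def read_barcode_list(
    path: str | os.PathLike, translation_path: str | os.PathLike | None = None
) -> BarcodeList:
    """Read a one-barcode-per-line list (optionally gzipped) and an optional 2-column translation TSV."""
    with _open_text(path) as fh:
        barcodes = tuple(line.strip() for line in fh if line.strip())
    translation = None
    if translation_path is not None:
        translation = {}
        with _open_text(translation_path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                k, v = line.split("\t")
                if k in translation:
                    raise ValueError(f"duplicate translation key {k!r}")
                translation[k] = v
    return BarcodeList(barcodes, translation)

def write_count_matrix(m: GuideCountMatrix, directory: str | os.PathLike) -> None:
    """Write ``matrix.mtx`` (integer, general; guides x cells) plus barcodes.tsv and features.tsv."""
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    coo = m.matrix.T.tocoo()  # on disk: features (guides) x barcodes
    scipy.io.mmwrite(
        os.path.join(directory, "matrix.mtx"), coo, field="integer", symmetry="general"
    )
    with open(os.path.join(directory, "barcodes.tsv"), "w") as fh:
        for bc in m.barcodes:
            fh.write(bc + "\n")
    with open(os.path.join(directory, "features.tsv"), "w") as fh:
        for g in m.guide_ids:
            fh.write(g + "\n")

def read_count_matrix(directory: str | os.PathLike) -> GuideCountMatrix:
    """Inverse of :func:`write_count_matrix`; errors if a companion file is missing."""
    directory = os.fspath(directory)
    for name in ("matrix.mtx", "barcodes.tsv", "features.tsv"):
        if not os.path.exists(os.path.join(directory, name)):
            raise FileNotFoundError(f"missing {name} in {directory}")
    mat = scipy.io.mmread(os.path.join(directory, "matrix.mtx"))
    with open(os.path.join(directory, "barcodes.tsv")) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    with open(os.path.join(directory, "features.tsv")) as fh:
        guide_ids = [line.strip() for line in fh if line.strip()]
    mat = sp.coo_matrix(mat) if not sp.issparse(mat) else mat
    return GuideCountMatrix(sp.csr_matrix(mat.T, dtype=np.int64), barcodes, guide_ids)

def _format_posterior(p: float | None) -> str:
    # >= 6 significant digits; NA for fallback calls with no posterior
    return "NA" if p is None else format(float(p), ".8g")

def write_calls(calls, path: str | os.PathLike) -> None:
    """Write per-(cell, guide) calls, sorted by (cell_barcode, guide_id)."""
    rows = sorted(calls, key=lambda c: (c.cell_barcode, c.guide_id))
    with open(path, "w") as fh:
        fh.write("cell_barcode\tguide_id\tcount\tposterior\texpressed\n")
        for c in rows:
            fh.write(
                f"{c.cell_barcode}\t{c.guide_id}\t{c.count}\t"
                f"{_format_posterior(c.posterior)}\t{c.expressed}\n"
            )

def read_calls(path: str | os.PathLike):
    """Read a calls TSV back into GuideCall records."""
    from .mixture import GuideCall

    df = pd.read_csv(path, sep="\t", dtype={"cell_barcode": str, "guide_id": str})
    out = []
    for _, row in df.iterrows():
        raw_p = row["posterior"]
        p = None if pd.isna(raw_p) or raw_p == "NA" else float(raw_p)
        expressed = row["expressed"]
        if isinstance(expressed, str):
            expressed = expressed.strip().lower() == "true"
        out.append(
            GuideCall(
                cell_barcode=row["cell_barcode"],
                guide_id=row["guide_id"],
                count=int(row["count"]),
                posterior=p,
                expressed=bool(expressed),
            )
        )
    return out

def write_assignments(assignments, path: str | os.PathLike) -> None:
    """Write per-cell assignments, sorted by cell barcode."""
    rows = sorted(assignments, key=lambda a: a.cell_barcode)
    with open(path, "w") as fh:
        fh.write("cell_barcode\tcalled_guides\tcategory\ttarget\tretained_for_analysis\n")
        for a in rows:
            guides = ",".join(sorted(a.called_guides))
            target = a.target if a.target is not None else "NA"
            fh.write(f"{a.cell_barcode}\t{guides}\t{a.category}\t{target}\t{a.retained_for_analysis}\n")
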