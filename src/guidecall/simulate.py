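"""Synthetic guide-capture data with the statistical structure the caller assumes.

Cells take up dual-guide lentiviral vectors at low multiplicity of infection
(Poisson uptake, MOI defaults to the low-MOI pooled-screen regime of 0.1).
Each protospacer of a received vector contributes high-mean negative
binomial UMI counts; every (cell, guide) pair additionally receives
zero-inflated negative binomial ambient counts, emulating guide transcripts
released into the cell suspension that end up captured in the wrong
droplets. Optionally, reads are emitted as gzipped FASTQ with a geometric
reads-per-UMI distribution and i.i.d. per-base substitution errors, so the
whole extraction pipeline can be exercised end to end against known truth.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .extract import ReadLayout
from .io import GuideCountMatrix, GuideLibrary

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_counts",
    "simulate_fastq",
    "example_library",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror a low-MOI pooled CRISPRi screen: MOI 0.1, well-separated
    expressing counts (mean 100) over a sparse ambient background
    (zero-inflation 0.7, mean 0.5).
    """

    n_cells: int = 5000
    lib: GuideLibrary | None = None  # None -> example_library()
    moi: float = 0.1
    mu_hi: float = 100.0
    r_hi: float = 5.0
    ambient_w0: float = 0.7
    ambient_mu: float = 0.5
    ambient_r: float = 1.0
    seed: int = 0
    # read-level parameters
    reads_per_umi: float = 3.0  # mean of the (1-based) geometric read count per UMI
    error_rate: float = 0.0  # per-base substitution probability
    read_length: int = 90
    barcode_read_length: int = 24
    layout: ReadLayout = field(default_factory=ReadLayout)

    def __post_init__(self) -> None:
        if self.moi < 0:
            raise ValueError("moi must be >= 0")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        if self.reads_per_umi < 1.0:
            raise ValueError("reads_per_umi must be >= 1")
        if not 0.0 <= self.ambient_w0 < 1.0:
            raise ValueError("ambient_w0 must be in [0, 1)")
        for name in ("mu_hi", "r_hi", "ambient_mu", "ambient_r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def resolved_library(self) -> GuideLibrary:
        return self.lib if self.lib is not None else example_library()


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated cohort."""

    received_vectors: dict[str, tuple[str, ...]]  # cell barcode -> vector ids
    true_category: dict[str, str]  # unassigned | singlet | doublet
    true_target: dict[str, str | None]
    signal: sp.csr_matrix  # cells x guides, counts from received vectors
    ambient: sp.csr_matrix  # cells x guides, background counts

    def category_of(self, barcode: str) -> str:
        return self.true_category[barcode]


def example_library(
    n_targets: int = 20, n_nt_vectors: int = 6, protospacer_length: int = 20, seed: int = 20
) -> GuideLibrary:
    """A synthetic dual-guide library shaped like a small pooled screen.

    ``n_targets`` gene-targeting dual-guide vectors (two protospacers per
    gene) plus ``n_nt_vectors`` non-targeting pairs; defaults give the
    26-vector / 52-guide / 20-target shape. Protospacer sequences are random
    distinct DNA. Each non-targeting vector carries its own target label so
    two different NT vectors in one cell read as incongruous.
    """
    rng = np.random.default_rng(seed)
    n_guides = 2 * (n_targets + n_nt_vectors)
    seqs: set[str] = set()
    while len(seqs) < n_guides:
        seqs.add("".join(rng.choice(["A", "C", "G", "T"], size=protospacer_length)))
    seq_list = sorted(seqs)
    rows = []
    k = 0
    for t in range(n_targets):
        gene = f"GENE{t + 1:02d}"
        for ps in (1, 2):
            rows.append((f"{gene}_PS{ps}", seq_list[k], gene, f"VEC{t + 1:02d}"))
            k += 1
    for t in range(n_nt_vectors):
        label = f"NT{t + 1:02d}"
        for ps in (1, 2):
            rows.append((f"{label}_PS{ps}", seq_list[k], label, f"VEC_NT{t + 1:02d}"))
            k += 1
    table = pd.DataFrame(rows, columns=["guide_id", "protospacer", "target", "vector_id"])
    return GuideLibrary(table)


def _random_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    out: dict[str, None] = {}
    while len(out) < n:
        block = rng.integers(0, 4, size=(n - len(out), length))
        for row in block:
            out.setdefault("".join("ACGT"[b] for b in row), None)
    return list(out)[:n]


def _sample_nb(rng: np.random.Generator, mu: float, r: float, size) -> np.ndarray:
    return rng.negative_binomial(n=r, p=r / (r + mu), size=size)


def simulate_counts(cfg: SimConfig) -> tuple[GuideCountMatrix, SimTruth]:
    """Draw a truth-labelled cell x guide UMI count matrix.

    Per cell, k ~ Poisson(moi) vectors are received (without replacement,
    capped at the library size); each contributes NB(mu_hi, r_hi) counts to
    each of its protospacers. Every (cell, guide) pair receives ZINB ambient
    counts on top. Fully reproducible from cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)
    lib = cfg.resolved_library()
    vectors = lib.vector_ids
    guide_index = {g: j for j, g in enumerate(lib.guide_ids)}
    vector_guides = {v: lib.guides_of_vector(v) for v in vectors}
    vector_targets = {
        v: {lib.target_of(g) for g in gs} for v, gs in vector_guides.items()
    }

    barcodes = _random_barcodes(cfg.n_cells, 16, rng)
    n_guides = lib.n_guides

    # ambient background for every (cell, guide)
    nonzero = rng.random((cfg.n_cells, n_guides)) >= cfg.ambient_w0
    ambient_dense = np.where(
        nonzero, _sample_nb(rng, cfg.ambient_mu, cfg.ambient_r, (cfg.n_cells, n_guides)), 0
    )

    uptake = np.minimum(rng.poisson(cfg.moi, size=cfg.n_cells), len(vectors))
    signal = sp.lil_matrix((cfg.n_cells, n_guides), dtype=np.int64)
    received: dict[str, tuple[str, ...]] = {}
    true_category: dict[str, str] = {}
    true_target: dict[str, str | None] = {}
    for i, bc in enumerate(barcodes):
        k = int(uptake[i])
        if k == 0:
            received[bc] = ()
            true_category[bc] = "unassigned"
            true_target[bc] = None
            continue
        chosen = tuple(rng.choice(len(vectors), size=k, replace=False))
        vecs = tuple(vectors[c] for c in chosen)
        received[bc] = vecs
        targets = set().union(*(vector_targets[v] for v in vecs))
        if len(targets) == 1:
            true_category[bc] = "singlet"
            true_target[bc] = next(iter(targets))
        else:
            true_category[bc] = "doublet"
            true_target[bc] = None
        for v in vecs:
            for g in vector_guides[v]:
                signal[i, guide_index[g]] += int(_sample_nb(rng, cfg.mu_hi, cfg.r_hi, None))

    signal = signal.tocsr()
    ambient = sp.csr_matrix(ambient_dense, dtype=np.int64)
    matrix = GuideCountMatrix(signal + ambient, barcodes, lib.guide_ids)
    truth = SimTruth(
        received_vectors=received,
        true_category=true_category,
        true_target=true_target,
        signal=signal,
        ambient=ambient,
    )
    return matrix, truth


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))


def simulate_fastq(
    matrix: GuideCountMatrix, cfg: SimConfig, out_dir: str | os.PathLike
) -> dict[str, str]:
    """Emit synchronized gzipped FASTQ streams realizing a count matrix.

    Every UMI of every (cell, guide) entry yields a geometric number of
    reads (mean cfg.reads_per_umi, minimum 1). The guide read carries
    UMI + protospacer + anchor per the layout with random filler; the
    barcode read carries the cell barcode. Substitution errors are i.i.d.
    at cfg.error_rate over all assembled bases. Output is byte-deterministic
    for a given config (gzip mtime pinned). A per-UMI truth table is written
    alongside.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    lib = cfg.resolved_library()
    layout = cfg.layout
    if layout.umi_stream != layout.protospacer_stream or layout.umi_offset != 0:
        raise ValueError(
            "simulate_fastq emits the UMI at the start of the protospacer stream; "
            "use a layout with umi_stream == protospacer_stream and umi_offset == 0"
        )
    ps_of = dict(zip(lib.table["guide_id"], lib.table["protospacer"]))
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)

    paths = {
        layout.barcode_stream: os.path.join(out_dir, f"{layout.barcode_stream}.fastq.gz"),
        layout.protospacer_stream: os.path.join(out_dir, f"{layout.protospacer_stream}.fastq.gz"),
    }
    truth_path = os.path.join(out_dir, "umi_truth.tsv")

    coo = matrix.matrix.tocoo()
    entries = sorted(zip(coo.row, coo.col, coo.data), key=lambda t: (t[0], t[1]))

    handles = {
        name: gzip.GzipFile(path, "wb", mtime=0) for name, path in paths.items()
    }
    read_id = 0
    try:
        with open(truth_path, "w") as truth_fh:
            truth_fh.write("cell_barcode\tguide_id\tumi\tn_reads\n")
            for i, j, count in entries:
                bc = matrix.barcodes[int(i)]
                guide = matrix.guide_ids[int(j)]
                ps = ps_of[guide]
                umis: set[str] = set()
                while len(umis) < count:
                    umis.add(_random_dna(layout.umi_length, rng))
                for umi in sorted(umis):
                    n_reads = int(rng.geometric(1.0 / cfg.reads_per_umi))
                    truth_fh.write(f"{bc}\t{guide}\t{umi}\t{n_reads}\n")
                    for _ in range(n_reads):
                        read_id += 1
                        rid = f"sim-{read_id}"
                        core = umi + ps + layout.anchor
                        filler = _random_dna(max(0, cfg.read_length - len(core)), rng)
                        guide_read = _mutate(core + filler, rng, cfg.error_rate)
                        bc_fill = _random_dna(
                            max(0, cfg.barcode_read_length - len(bc)), rng
                        )
                        bc_read = _mutate(bc + bc_fill, rng, cfg.error_rate)
                        for name, seq in (
                            (layout.barcode_stream, bc_read),
                            (layout.protospacer_stream, guide_read),
                        ):
                            rec = f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n"
                            handles[name].write(rec.encode())
    finally:
        for h in handles.values():
            h.close()
    return {**paths, "truth": truth_path}
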