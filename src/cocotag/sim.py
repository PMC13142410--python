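"""Synthetic-data generators with ground truth for every pipeline input.

Each generator is a pure function of (config, seed): reads with known
barcode assignments over the dual 8x12 plate scheme; pseudobulk gene-score
matrices drawn from two-component log-scale mixtures with planted chromatin
states; low-dimensional embeddings with matched same-cell pairs and planted
doublet-enriched neighborhoods; and summit/fragment sets with planted
promoter and lineage-specific enhancer elements.  The generators emulate
the statistical structure the estimators assume — mixture-separated scores,
Gaussian cluster blobs, block-concentrated fragment signal — not sequencing
chemistry or chromatin biology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from cocotag.barcodes import STREAMS, BarcodeScheme, cell_barcode, well_id

K4_MARKS = ("H3K4me1", "H3K4me2", "H3K4me3")
STATES = ("active", "repressed", "bivalent", "unmarked", "other")

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Shared knobs for the synthetic generators.

    ``score_mixture`` maps each mark to (mu_low, mu_high, sigma) on the
    log10(score + 0.1) scale; defaults put the components 4 sigma apart.
    ``state_fractions`` are the planted chromatin-state frequencies.
    ``barcode_error_rate`` is the expected number of substitutions per
    barcode (each base is substituted independently at rate/length).
    """

    seed: int = 0
    n_cells: int = 200
    n_genes: int = 500
    n_clusters: int = 6
    read_length: int = 50
    mean_reads_per_cell: float = 50.0
    barcode_error_rate: float = 0.0
    stream_probs: tuple[float, float, float, float] = (0.4, 0.4, 0.1, 0.1)
    state_fractions: dict = field(
        default_factory=lambda: {
            "active": 0.30,
            "repressed": 0.25,
            "bivalent": 0.15,
            "unmarked": 0.25,
            "other": 0.05,
        }
    )
    score_mixture: dict = field(
        default_factory=lambda: {
            mark: (0.0, 2.0, 0.5)
            for mark in (*K4_MARKS, "H3K27me3", "cooccupancy")
        }
    )
    # embedding
    n_dims: int = 15
    pair_displacement: float = 0.5
    cluster_sd: float = 1.0
    cluster_spread: float = 20.0
    doublet_fraction: float = 0.30       # doublet rate inside the planted neighborhood
    background_doublet_rate: float = 0.02
    doublet_blob_cells: int = 150
    # summits / elements
    n_summits: int = 300
    n_lineages: int = 2
    chrom: str = "chr1"
    chrom_length: int = 10_000_000
    element_spacing: int = 20_000
    high_frags: float = 200.0
    low_frags: float = 5.0
    fragment_jitter: int = 300

    def __post_init__(self) -> None:
        for name, p in (("barcode_error_rate", self.barcode_error_rate),
                        ("doublet_fraction", self.doublet_fraction),
                        ("background_doublet_rate", self.background_doublet_rate)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        tot = sum(self.state_fractions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"state_fractions must sum to 1, got {tot}")
        for mark, (lo, hi, sd) in self.score_mixture.items():
            if not lo < hi:
                raise ValueError(f"score_mixture[{mark}]: mu_low must be < mu_high")
            if sd <= 0:
                raise ValueError(f"score_mixture[{mark}]: sigma must be > 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        data = json.loads(Path(path).read_text())
        for key in ("stream_probs",):
            if key in data:
                data[key] = tuple(data[key])
        if "score_mixture" in data:
            data["score_mixture"] = {k: tuple(v) for k, v in data["score_mixture"].items()}
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASE_ARR[rng.integers(0, 4, size=length)]).decode()

def _corrupt(rng: np.random.Generator, seq: str, per_barcode_rate: float) -> tuple[str, bool]:
    """Substitute each base independently at per_barcode_rate/len(seq)."""
    if per_barcode_rate <= 0:
        return seq, False
    q = per_barcode_rate / len(seq)
    hits = np.nonzero(rng.random(len(seq)) < q)[0]
    if hits.size == 0:
        return seq, False
    arr = bytearray(seq.encode())
    for i in hits:
        old = arr[i]
        choices = [b for b in b"ACGT" if b != old]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.decode(), True


def simulate_reads(
    config: SimConfig, scheme: BarcodeScheme, out_dir: str | Path | None = None
) -> tuple[dict[str, list[tuple[str, str, str]]], pd.DataFrame]:
    """Simulate paired genomic reads plus two index reads per record.

    Returns ``(fastq, truth)`` where ``fastq`` maps ``{"R1","R2","I1","I2"}``
    to lists of (header, seq, qual) records and ``truth`` lists per read the
    barcode indices, intended stream, true cell barcode and whether any of
    its four barcodes was corrupted.  If ``out_dir`` is given the four FASTQ
    files and the truth TSV are also written there.
    """
    rng = np.random.default_rng(config.seed)
    n_wells = len(scheme.p5_wells)

    # assign each cell a plate well (row 1-8, col 1-12) and unique nanowell
    wells = rng.integers(0, 96, size=config.n_cells)
    nanos = rng.choice(n_wells * n_wells, size=config.n_cells, replace=False) \
        if config.n_cells <= n_wells * n_wells else rng.integers(0, n_wells * n_wells, size=config.n_cells)

    fastq: dict[str, list[tuple[str, str, str]]] = {k: [] for k in ("R1", "R2", "I1", "I2")}
    rows = []
    read_no = 0
    probs = np.asarray(config.stream_probs, dtype=float)
    probs = probs / probs.sum()
    for c in range(config.n_cells):
        row = int(wells[c]) // 12 + 1          # s5 rank 1-8
        col = int(wells[c]) % 12 + 1           # s7 rank 1-12
        p5 = int(nanos[c]) // n_wells + 1
        p7 = int(nanos[c]) % n_wells + 1
        n_reads = rng.poisson(config.mean_reads_per_cell)
        streams = rng.choice(4, size=n_reads, p=probs)
        for s_i in streams:
            stream = STREAMS[s_i]
            s5 = row if stream in ("target1", "co1") else row + 8
            s7 = col if stream in ("target1", "co2") else col + 12
            read_no += 1
            rid = f"read{read_no}"
            s7_seq, e1 = _corrupt(rng, scheme.s7[s7 - 1], config.barcode_error_rate)
            p7_seq, e2 = _corrupt(rng, scheme.p7_wells[p7 - 1], config.barcode_error_rate)
            s5_seq, e3 = _corrupt(rng, scheme.s5[s5 - 1], config.barcode_error_rate)
            p5_seq, e4 = _corrupt(rng, scheme.p5_wells[p5 - 1], config.barcode_error_rate)
            qual_g = "I" * config.read_length
            fastq["R1"].append((rid, _random_seq(rng, config.read_length), qual_g))
            fastq["R2"].append((rid, _random_seq(rng, config.read_length), qual_g))
            fastq["I1"].append((rid, s7_seq + p7_seq, "I" * (len(s7_seq) + len(p7_seq))))
            fastq["I2"].append((rid, s5_seq + p5_seq, "I" * (len(s5_seq) + len(p5_seq))))
            rows.append(
                {
                    "read": rid,
                    "s5_index": s5,
                    "s7_index": s7,
                    "p5_index": p5,
                    "p7_index": p7,
                    "stream": stream,
                    "cell_barcode": cell_barcode(well_id(s5, s7), p5, p7),
                    "n_corrupted_barcodes": int(e1) + int(e2) + int(e3) + int(e4),
                }
            )
    truth = pd.DataFrame(
        rows,
        columns=[
            "read", "s5_index", "s7_index", "p5_index", "p7_index",
            "stream", "cell_barcode", "n_corrupted_barcodes",
        ],
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for key, recs in fastq.items():
            with open(out_dir / f"{key}.fastq", "w") as fh:
                for h, s, q in recs:
                    fh.write(f"@{h}\n{s}\n+\n{q}\n")
        truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return fastq, truth


# ---------------------------------------------------------------------------
# gene scores
# ---------------------------------------------------------------------------

# which component each mark draws from, per planted state
_STATE_RULE = {
    "active":    {"K4": "high", "H3K27me3": "low",  "cooccupancy": "low"},
    "repressed": {"K4": "low",  "H3K27me3": "high", "cooccupancy": "low"},
    "bivalent":  {"K4": "high", "H3K27me3": "high", "cooccupancy": "high"},
    "unmarked":  {"K4": "low",  "H3K27me3": "low",  "cooccupancy": "low"},
    "other":     {"K4": "high", "H3K27me3": "high", "cooccupancy": "low"},
}


def simulate_genescores(config: SimConfig) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Pseudobulk gene-score matrices with planted chromatin states.

    For each (gene, cluster) a state is drawn from ``state_fractions``; each
    mark's log10(score+0.1) value is drawn from its high or low mixture
    component according to the state rule (co-occupancy is high only for
    bivalent).  Returns ``(matrices, truth)`` where ``matrices`` maps mark
    name (three H3K4 marks, H3K27me3, cooccupancy) to a gene x cluster
    DataFrame of scores and ``truth`` is a long table (gene, cluster, state).
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"gene{i}" for i in range(config.n_genes)]
    clusters = [f"C{j + 1}" for j in range(config.n_clusters)]
    names = list(config.state_fractions)
    p = np.array([config.state_fractions[s] for s in names])
    states = rng.choice(len(names), size=(config.n_genes, config.n_clusters), p=p)

    matrices: dict[str, pd.DataFrame] = {}
    for mark in (*K4_MARKS, "H3K27me3", "cooccupancy"):
        lo, hi, sd = config.score_mixture[mark]
        role = "K4" if mark in K4_MARKS else mark
        mu = np.empty_like(states, dtype=float)
        for k, sname in enumerate(names):
            level = _STATE_RULE[sname][role]
            mu[states == k] = hi if level == "high" else lo
        x = rng.normal(mu, sd)
        scores = np.maximum(10.0 ** x - 0.1, 0.0)
        matrices[mark] = pd.DataFrame(scores, index=genes, columns=clusters)

    truth = pd.DataFrame(
        [
            {"gene": g, "cluster": c, "state": names[states[i, j]]}
            for i, g in enumerate(genes)
            for j, c in enumerate(clusters)
        ]
    )
    return matrices, truth


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

def simulate_embedding(
    config: SimConfig, n_blobs: int = 4
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Gaussian cluster blobs with matched pairs and a planted doublet blob.

    Returns ``(coords, pair_map, meta)``:

    - ``coords``: (2*n_cells + doublet_blob_cells) x n_dims array; the first
      ``n_cells`` rows are primary profiles, the next ``n_cells`` rows their
      matched partners (same cell, re-profiled) displaced by
      ``pair_displacement`` x isotropic noise, and the remaining rows form a
      spatially compact blob whose cells carry genotype-doublet labels at
      rate ``doublet_fraction`` (background cells at
      ``background_doublet_rate``).
    - ``pair_map``: (n_cells, 2) index pairs (i, partner_of_i).
    - ``meta``: per-row cluster label, genotype status
      (``singlet``/``doublet``), and ``planted_doublet_blob`` flag.
    """
    rng = np.random.default_rng(config.seed)
    n, d = config.n_cells, config.n_dims
    centers = rng.normal(0.0, config.cluster_spread, size=(n_blobs, d))
    labels = rng.integers(0, n_blobs, size=n)
    base = centers[labels] + rng.normal(0.0, config.cluster_sd, size=(n, d))
    partners = base + rng.normal(0.0, config.cluster_sd, size=(n, d)) * config.pair_displacement

    nb = config.doublet_blob_cells
    # doublet neighborhood: midpoint of two centroids (how synthetic doublets
    # project) plus local noise — compact and separated from the blobs
    blob_center = (centers[0] + centers[1 % n_blobs]) / 2.0
    blob = blob_center + rng.normal(0.0, config.cluster_sd, size=(nb, d))

    coords = np.vstack([base, partners, blob])
    pair_map = np.column_stack([np.arange(n), np.arange(n) + n])

    status = np.where(
        rng.random(coords.shape[0]) < config.background_doublet_rate, "doublet", "singlet"
    ).astype(object)
    if nb:
        status[2 * n:] = np.where(rng.random(nb) < config.doublet_fraction, "doublet", "singlet")
    meta = pd.DataFrame(
        {
            "cell": [f"cell{i}" for i in range(coords.shape[0])],
            "cluster": [f"B{l}" for l in labels] * 2 + ["doubletblob"] * nb,
            "genotype_status": status,
            "planted_doublet_blob": [False] * (2 * n) + [True] * nb,
        }
    )
    return coords, pair_map, meta


# ---------------------------------------------------------------------------
# summits / elements
# ---------------------------------------------------------------------------

def simulate_summits(
    config: SimConfig,
) -> tuple[dict[str, pd.DataFrame], dict[tuple[str, str], pd.DataFrame], pd.DataFrame]:
    """Planted promoter and lineage-specific enhancer elements.

    Elements are laid out along one synthetic chromosome: one third are
    promoters placed at planted TSSs (H3K4me3-high in every cluster), the
    rest are distal enhancers split across ``n_lineages`` lineages
    (H3K4me1-high only in their own lineage's cluster).  Returns:

    - ``summits``: per-lineage summit tables (chrom, start, end, name,
      score) — every element is called in every lineage, with small
      positional jitter, so cross-lineage merging is exercised;
    - ``fragments``: maps (cluster, mark) to fragment BED tables
      concentrated around elements according to the planted signal plan;
    - ``truth``: per element its position, class label and TSS (promoters).
    """
    rng = np.random.default_rng(config.seed)
    n_el = config.n_summits
    n_lin = config.n_lineages
    classes = ["promoter"] + [f"enhancer_L{k + 1}" for k in range(n_lin)]
    # round-robin class assignment -> balanced classes
    cls = np.array([classes[i % len(classes)] for i in range(n_el)], dtype=object)
    pos = (np.arange(n_el) + 1) * config.element_spacing
    if pos[-1] + 10_000 > config.chrom_length:
        raise ValueError("chrom_length too small for n_summits * element_spacing")

    truth = pd.DataFrame(
        {
            "element": [f"el{i}" for i in range(n_el)],
            "chrom": config.chrom,
            "pos": pos,
            "cls": cls,
            "tss": np.where(cls == "promoter", pos, -1),
        }
    )

    summits: dict[str, pd.DataFrame] = {}
    for k in range(n_lin):
        jitter = rng.integers(-20, 21, size=n_el)
        score = rng.uniform(50, 500, size=n_el).round(2)
        s = pd.DataFrame(
            {
                "chrom": config.chrom,
                "start": pos + jitter,
                "end": pos + jitter + 1,
                "name": [f"L{k + 1}_summit{i}" for i in range(n_el)],
                "score": score,
            }
        )
        summits[f"L{k + 1}"] = s.sort_values(["chrom", "start"]).reset_index(drop=True)

    marks = ("H3K4me3", "H3K4me1")
    fragments: dict[tuple[str, str], pd.DataFrame] = {}
    for k in range(n_lin):
        cluster = f"L{k + 1}"
        for mark in marks:
            if mark == "H3K4me3":
                high = cls == "promoter"
            else:
                high = cls == f"enhancer_L{k + 1}"
            lam = np.where(high, config.high_frags, config.low_frags)
            counts = rng.poisson(lam)
            centers = np.repeat(pos, counts)
            starts = centers + rng.integers(
                -config.fragment_jitter, config.fragment_jitter, size=centers.size
            )
            lengths = rng.integers(80, 400, size=centers.size)
            starts = np.clip(starts, 0, config.chrom_length - 1)
            ends = np.minimum(starts + lengths, config.chrom_length)
            frag = pd.DataFrame(
                {
                    "chrom": config.chrom,
                    "start": starts,
                    "end": ends,
                    "cell": cluster,
                }
            ).sort_values(["chrom", "start", "end"]).reset_index(drop=True)
            fragments[(cluster, mark)] = frag
    return summits, fragments, truth
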