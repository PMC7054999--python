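"""Two-species Ribo-Seq read simulator with a yeast spike-in.

The simulator emulates a ribosome-profiling experiment in which equal
amounts of yeast lysate are spiked into control (DMSO) and CDK1-inhibited
(Ro3306) samples before footprint generation.  It emits four FASTQ files
(footprint/input x DMSO/Ro3306), a transcript FASTA, an ORF annotation
table, category gene lists, and a ground-truth record.

Read model:

* footprint reads are ~29-nt fragments (Gaussian length, clipped to the
  25-35-nt size selection) whose 5' ends fall inside the CDS, in frame 0
  with probability ``frame0_fraction`` (remainder split evenly over frames
  1 and 2);
* input reads are uniform fragments over the whole transcript;
* every read is wrapped with four random nucleotides on each end plus a
  fixed 12-nt 3' adapter, and written with a constant Phred+33 quality;
* a small fraction of reads comes from human rRNA/tRNA contaminants.

Treatment acts multiplicatively on the per-mRNA footprint sampling rate of
human genes (``global_suppression``, times ``top_extra_suppression`` for
5'TOP genes); yeast rates and all input rates are identical across
conditions, so spike-in normalization — but not library-size normalization —
can recover the absolute suppression.  Presets: ``null`` (no suppression),
``cdk1i-global`` (0.5 global), ``cdk1i-top`` (0.5 global, 0.4 extra on TOP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

ADAPTER = "TGGAATTCTCGG"  # fixed 12-nt 3' adapter constant
N_RANDOM = 4              # random nucleotides on each end of the insert
_BASES = np.array(list("ACGT"))

CONTROL, TREATED = "DMSO", "Ro3306"
SAMPLES = [("footprint", CONTROL), ("footprint", TREATED),
           ("input", CONTROL), ("input", TREATED)]


@dataclass(frozen=True)
class RiboSimConfig:
    n_human_genes: int = 300
    n_yeast_genes: int = 20
    category_fractions: Mapping[str, float] = field(default_factory=lambda: {
        "TOP": 0.15, "IRES": 0.10, "mito_rp": 0.05, "other": 0.70})
    utr5_len: tuple = (30, 90)
    cds_len: tuple = (300, 900)
    utr3_len: tuple = (50, 150)
    footprint_len_mean: float = 29.0
    footprint_len_sd: float = 1.5
    footprint_len_range: tuple = (25, 35)  # gel size selection
    frame0_fraction: float = 0.8
    n_footprint_reads: int = 200_000
    n_input_reads: int = 200_000
    spike_in_fraction: float = 0.02
    global_suppression: float = 1.0
    top_extra_suppression: float = 1.0
    rrna_trna_contam_fraction: float = 0.05
    expression_sd: float = 0.75  # log scale, per-gene expression spread
    seed: int = 0

    def __post_init__(self) -> None:
        fr = dict(self.category_fractions)
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError("category fractions must sum to 1")
        for name in ("frame0_fraction", "spike_in_fraction",
                     "rrna_trna_contam_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.cds_len[0] < self.footprint_len_range[1]:
            raise ValueError("minimum CDS length must fit the longest footprint")
        if self.global_suppression <= 0 or self.top_extra_suppression <= 0:
            raise ValueError("suppression factors must be positive")


_PRESETS = {
    "null": dict(global_suppression=1.0, top_extra_suppression=1.0),
    "cdk1i-global": dict(global_suppression=0.5, top_extra_suppression=1.0),
    "cdk1i-top": dict(global_suppression=0.5, top_extra_suppression=0.4),
}


def riboseq_preset(name: str, **overrides) -> RiboSimConfig:
    """Named treatment presets; keyword overrides adjust any other field."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    return RiboSimConfig(**{**_PRESETS[name], **overrides})


@dataclass
class RiboSimOutput:
    directory: Path
    fastq: dict            # (assay, condition) -> Path
    reference_fasta: Path
    annotation: Path
    top_genes: Path
    ires_genes: Path
    mito_rp_genes: Path
    truth: "SyntheticTruth"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _build_references(config: RiboSimConfig, rng: np.random.Generator):
    """Transcript records: (id, gene, species, class, cds_start, cds_end, seq)."""
    records = []
    categories = {}
    cat_names = list(config.category_fractions)
    cat_probs = np.array([config.category_fractions[c] for c in cat_names])
    for i in range(config.n_human_genes):
        u5 = int(rng.integers(*config.utr5_len))
        cds = int(rng.integers(config.cds_len[0] // 3, config.cds_len[1] // 3)) * 3
        u3 = int(rng.integers(*config.utr3_len))
        seq = _random_seq(rng, u5 + cds + u3)
        gene = f"GENE_HS_{i:04d}"
        records.append((f"TX_HS_{i:04d}", gene, "human", "mRNA", u5, u5 + cds, seq))
        categories[gene] = cat_names[int(rng.choice(len(cat_names), p=cat_probs))]
    for i in range(config.n_yeast_genes):
        u5 = int(rng.integers(*config.utr5_len))
        cds = int(rng.integers(config.cds_len[0] // 3, config.cds_len[1] // 3)) * 3
        u3 = int(rng.integers(*config.utr3_len))
        seq = _random_seq(rng, u5 + cds + u3)
        records.append((f"TX_SC_{i:04d}", f"GENE_SC_{i:04d}", "yeast", "mRNA",
                        u5, u5 + cds, seq))
    for i, length in enumerate((1800, 1500, 120)):
        records.append((f"RRNA_HS_{i}", f"RRNA_HS_{i}", "human", "rRNA",
                        -1, -1, _random_seq(rng, length)))
    for i in range(5):
        records.append((f"TRNA_HS_{i}", f"TRNA_HS_{i}", "human", "tRNA",
                        -1, -1, _random_seq(rng, 72)))
    return records, categories


def _sample_footprints(rng, seq, cds_start, cds_end, n, config):
    """5'-end positions and lengths for n footprint reads on one mRNA."""
    lo, hi = config.footprint_len_range
    lengths = np.clip(np.rint(rng.normal(config.footprint_len_mean,
                                         config.footprint_len_sd, n)),
                      lo, hi).astype(int)
    f0 = config.frame0_fraction
    frames = rng.choice(3, size=n, p=[f0, (1 - f0) / 2, (1 - f0) / 2])
    kmax = (cds_end - cds_start - lengths - frames) // 3
    k = rng.integers(0, kmax + 1)
    starts = cds_start + frames + 3 * k
    return starts, lengths


def _sample_uniform(rng, seq_len, n, config):
    lo, hi = config.footprint_len_range
    lengths = np.clip(np.rint(rng.normal(config.footprint_len_mean,
                                         config.footprint_len_sd, n)),
                      lo, hi).astype(int)
    lengths = np.minimum(lengths, seq_len)
    starts = rng.integers(0, seq_len - lengths + 1)
    return starts, lengths


def _write_fastq(path: Path, reads, rng: np.random.Generator, sample: str):
    """Wrap inserts (4 random nt each side + adapter) and write 4-line FASTQ."""
    n = len(reads)
    wrap = "".join(_BASES[rng.integers(0, 4, size=8 * max(n, 1))])
    with open(path, "w") as fh:
        for i, insert in enumerate(reads):
            seq = wrap[8 * i:8 * i + 4] + insert + wrap[8 * i + 4:8 * i + 8] + ADAPTER
            fh.write(f"@{sample}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def gen_riboseq(config: RiboSimConfig, out_dir: str | Path) -> RiboSimOutput:
    """Generate the four FASTQ files, references, annotation, and truth."""
    from . import SyntheticTruth

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    records, categories = _build_references(config, rng)
    mrna = [r for r in records if r[3] == "mRNA"]
    contam = [r for r in records if r[3] != "mRNA"]

    human_idx = [i for i, r in enumerate(mrna) if r[2] == "human"]
    yeast_idx = [i for i, r in enumerate(mrna) if r[2] == "yeast"]
    w = np.exp(rng.normal(0.0, config.expression_sd, len(mrna)))
    # scale yeast weights so that, in the control condition, the yeast share
    # of mRNA-mapped reads equals the spike-in fraction
    f = config.spike_in_fraction
    w[yeast_idx] *= (f / (1 - f)) * w[human_idx].sum() / w[yeast_idx].sum()

    is_top = np.array([categories.get(r[1]) == "TOP" for r in mrna])
    is_human = np.array([r[2] == "human" for r in mrna])
    supp = np.where(is_human,
                    config.global_suppression
                    * np.where(is_top, config.top_extra_suppression, 1.0),
                    1.0)

    fastq_paths = {}
    census = {}
    for assay, condition in SAMPLES:
        n_reads = (config.n_footprint_reads if assay == "footprint"
                   else config.n_input_reads)
        n_contam = int(round(n_reads * config.rrna_trna_contam_fraction))
        n_mrna = n_reads - n_contam
        weights = w.copy()
        if assay == "footprint" and condition == TREATED:
            weights = weights * supp
        counts = rng.multinomial(n_mrna, weights / weights.sum())
        contam_lens = np.array([len(r[6]) for r in contam], dtype=float)
        contam_counts = rng.multinomial(n_contam,
                                        contam_lens / contam_lens.sum())
        inserts = []
        for (tid, gene, species, tclass, cs, ce, seq), c in zip(mrna, counts):
            if c == 0:
                continue
            if assay == "footprint":
                starts, lengths = _sample_footprints(rng, seq, cs, ce, c, config)
            else:
                starts, lengths = _sample_uniform(rng, len(seq), c, config)
            inserts.extend(seq[s:s + L] for s, L in zip(starts, lengths))
        for (tid, gene, species, tclass, cs, ce, seq), c in zip(contam,
                                                                contam_counts):
            if c == 0:
                continue
            starts, lengths = _sample_uniform(rng, len(seq), c, config)
            inserts.extend(seq[s:s + L] for s, L in zip(starts, lengths))
        sample = f"{assay}_{condition}"
        path = out / f"{sample}.fastq"
        _write_fastq(path, inserts, rng, sample)
        fastq_paths[(assay, condition)] = path
        census[sample] = len(inserts)

    fasta = out / "reference.fasta"
    with open(fasta, "w") as fh:
        for tid, gene, species, tclass, cs, ce, seq in records:
            fh.write(f">{tid}\n")
            for j in range(0, len(seq), 80):
                fh.write(seq[j:j + 80] + "\n")
    annotation = out / "annotation.tsv"
    pd.DataFrame(
        [(tid, gene, species, tclass,
          cs if cs >= 0 else "", ce if ce >= 0 else "")
         for tid, gene, species, tclass, cs, ce, seq in records],
        columns=["transcript_id", "gene_symbol", "species", "class",
                 "cds_start", "cds_end"],
    ).to_csv(annotation, sep="\t", index=False)

    list_paths = {}
    for cat, fname in (("TOP", "top_genes.txt"), ("IRES", "ires_genes.txt"),
                       ("mito_rp", "mito_rp_genes.txt")):
        p = out / fname
        p.write_text("".join(f"{g}\n" for g, c in sorted(categories.items())
                             if c == cat))
        list_paths[cat] = p

    gene_truth = pd.DataFrame({
        "gene_symbol": [r[1] for r in mrna],
        "species": [r[2] for r in mrna],
        "category": [categories.get(r[1], "") for r in mrna],
        "expression_weight": w,
        "fp_suppression": supp,
        "expected_delta_rd": supp,  # input rates are condition-invariant
    })
    truth = SyntheticTruth(
        assay="riboseq",
        params={"adapter": ADAPTER, "n_random": N_RANDOM,
                "read_census": census,
                "global_suppression": config.global_suppression,
                "top_extra_suppression": config.top_extra_suppression,
                "spike_in_fraction": config.spike_in_fraction,
                "seed": config.seed},
        tables={"genes": gene_truth},
    )
    truth.write(out)
    return RiboSimOutput(out, fastq_paths, fasta, annotation,
                         list_paths["TOP"], list_paths["IRES"],
                         list_paths["mito_rp"], truth)
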