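# transquant

Multi-assay quantification of cellular protein-synthesis rates.

Studies of translational control — for example, how cell-cycle kinase
activity couples proliferation with protein synthesis — rest on a handful of
bespoke quantification procedures scattered across screening, biochemistry,
sequencing, proteomics, and imaging. `transquant` implements that pipeline
as a tested library, together with synthetic-data generators that emit
matched ground truth, so every analysis step can be validated for parameter
recovery without access to raw experimental data.

## What it computes

**Stress-granule (SG) screen scoring** (`transquant.screen`).  For a gene
knocked down with four independent siRNAs, with per-well counts of
SG-containing cells `c_1..c_4`:

    SG score = (Σ_i c_i) × #{i : c_i ≥ 1}

Candidates: score > 10 with ≥ 2 SG-causing siRNAs, or score > 40 with one
(strict inequalities).

**Polysome profiles** (`transquant.polysome`).  From an A254 sucrose-gradient
trace, after baseline correction and automatic 80S-peak/boundary detection:

    % polysomal = 100 · AUC(beyond first minimum after 80S) / AUC(total)

plus 80S-peak trace alignment, treated/control fold changes with one-tailed
t tests, and HBB2-spike-normalized fraction-wise qPCR distributions
(relative amount per fraction `E^−(Ct_f − Ct_spike,f)`).

**Ribosome density (Ribo-Seq)** (`transquant.riboseq`).  Reads are trimmed
(3′ adapter, 4 random nt per end), classified hierarchically
(tRNA → rRNA → human+yeast transcriptome → unmapped) with an exact-match
index, and counted per gene when all hits are ORF-contained and share one
gene symbol.  With a yeast lysate spiked equally into both conditions,
per-sample scale factors equalize yeast ORF totals, and for each human gene

    RD = footprints_norm / ORF-spanning input reads_norm,
    ΔRD = RD_treated / RD_control.

The summary reports the unweighted gene-mean RD and the pooled ΣFP/Σinput
aggregate, per-category (5′TOP / IRES / mito-RP / other) median log2 ΔRD
with KS distances, median-of-ratios size factors, and a QC battery (length
histograms, frame periodicity, start/stop metagenes, replicate correlation).

**SILAC phosphoproteomics** (`transquant.phospho`).  Heavy/light ratios are
oriented by each replicate's label swap (reciprocal when the treated
condition was light), normalized to the corresponding total-protein ratio,
and sites are called treatment-sensitive when every replicate clears a
twofold cutoff concordantly.

**Puromycin imaging** (`transquant.imaging`).  Nuclei from the Hoechst
channel (threshold + components), cell ROIs grown into the eIF3B foreground
(nearest-seed assignment), per-ROI mean puromycin intensity normalized to
the control-condition mean; plus Ponceau-normalized lane densitometry for
Western blots.

**Statistics** (`transquant.stats`).  One-tailed Welch, paired t, and ratio
paired t (log-transformed relative values) tests, with explicit directions.

## Worked example

Simulate a two-condition ribosome-profiling experiment in which every human
mRNA's footprint rate is halved by treatment (5′TOP mRNAs not additionally
affected), then quantify it both ways:

```python
from transquant.simulate import riboseq_preset, gen_riboseq
from transquant.simulate.riboseq import ADAPTER
from transquant.riboseq import ReferenceSet, run_pipeline

sim = gen_riboseq(riboseq_preset("cdk1i-global", seed=1), "scratch/demo")
refs = ReferenceSet.from_files(sim.reference_fasta, sim.annotation,
                               sim.top_genes, sim.ires_genes, sim.mito_rp_genes)

spike = run_pipeline(sim.fastq, refs, ADAPTER, "DMSO", "Ro3306")
print(round(spike.summary.fold_reduction, 3))        # 2.033
naive = run_pipeline(sim.fastq, refs, ADAPTER, "DMSO", "Ro3306",
                     normalization="library-size")
print(round(naive.summary.fold_change, 3))           # 0.982
```

The spike-normalized mean RD falls twofold (fold reduction 2.033 against a
simulated truth of 2.0), while library-size normalization reports an
apparent fold change of 0.982 — i.e. no change.  Because both libraries are
sequenced to the same depth, a uniform suppression is invisible without the
spike-in: that contrast is the core argument for the spike-in design.

The same objects expose the per-gene table (`spike.rd_table`), category
medians (`spike.categories`), and QC
(`spike.samples[("footprint", "DMSO")].qc`).  A `transquant` console script
wraps the common operations (`transquant simulate riboseq --preset
cdk1i-global …`, `transquant riboseq-rd`, `transquant screen-score`,
`transquant polysome-quant`, `transquant phospho-norm`, `transquant stat`).

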