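# tcr-track

Annotating T helper (Th) cell states in single-cell RNA-seq data is usually
done from transcriptomes alone, which separates the classic, surface-marker
sorted subsets (Th1, Th1-17, Th17, Th22, Th2, Th2a, Tfh, Treg) poorly.
`tcrtrack` implements an alternative: because T cells of one clone share a
unique TCR rearrangement, the CDR3β nucleotide sequence acts as a natural
clonal barcode. Bulk TCRβ repertoires sequenced from FACS-sorted Th subsets
can therefore be mapped, clone by clone and within each donor, onto
scRNA-seq/scTCR-seq cells — positioning each sorted phenotype inside the
transcriptomic cluster landscape without using expression at all.

The package is a library plus a `tcrtrack` CLI for immunologists working
with paired scRNA-seq/scTCR-seq data and sorted-subset bulk repertoires
(VDJtools/AIRR/MiXCR-style tables, 10x `filtered_contig_annotations.csv`).

## Method

For donor *d*, each sorted subset repertoire is restricted to its top-500
CDR3β nucleotide clonotypes; a cell of donor *d* is assigned to subset *j*
when its resolved TCRβ CDR3 nucleotide sequence exactly matches one of those
clonotypes. Per-cell chain resolution keeps, per chain, the contig with the
highest UMI count among productive, V/J-spanning contigs without stop
codons. With *n<sub>ij</sub>* matched cells of subset *j* in cluster *i*,
the mapping is summarized by the stained proportion of the cluster
(*n<sub>ij</sub>* / cluster size) and the subset's distribution over
clusters *p<sub>ij</sub>* = *n<sub>ij</sub>* / Σ<sub>i</sub>
*n<sub>ij</sub>*. Mapping focus is scored with the normalized
Shannon–Wiener index

&nbsp;&nbsp;&nbsp;&nbsp;*S<sub>j</sub>* = −Σ<sub>i</sub> *p<sub>ij</sub>*
ln *p<sub>ij</sub>* / ln *N*,

with *N* the number of clusters holding at least one match; subsets with
fewer than eight cells are excluded. Lower *S* means a more focused mapping.

Accompanying statistics: per-cluster clonality (unique CDR3β / cell count),
pairwise clonal overlap between clusters of one donor via the D metric
*D* = |A∩B| / (|A|·|B|) displayed as log₂(1 + 10⁶·D), and a
shared-clonotype partition of two sorted repertoires (top-2,000 slices)
that keeps an overlapping clonotype as genuinely shared when the standard
deviation of its two frequencies, |f_A − f_B|/√2, is below 0.001. A
CITE-seq comparator arm CLR-normalizes ADT counts, gates cells through the
classic sequential marker hierarchy (CD25/CD127 → CXCR5 → CCR10 →
CCR6/CXCR3/CCR4/CRTh2), optimizes the gate thresholds by minimizing the
same mean Shannon index, and is scored identically so the two annotation
routes are directly comparable.

A seeded synthetic-data generator produces donor-structured clonal
repertoires (power-law clone sizes), subset-specific cluster programs,
sorting impurity, single-cell capture with decoy contigs, and
negative-binomial ADT counts in exactly the file formats the readers
accept, so the whole pipeline is testable end to end without any download.

## Worked example

```python
from tcrtrack import SyntheticConfig, simulate_dataset, run_tcr_track

cfg = SyntheticConfig(seed=1)            # 3 donors x 2,000 cells, 8 subsets
ds = simulate_dataset(cfg)
result, matches = run_tcr_track(ds.bulk, ds.contigs, ds.meta,
                                subsample_n=None, seed=1)
print(result.shannon)
for s in cfg.subsets:
    print(s, "->", result.size.loc[s].idxmax())
```

prints

```
   subset         S  n_cells  n_clusters  defined
0     Tfh  0.282780      638          16     True
1     Th1  0.271019      848          16     True
2  Th1-17  0.261247      555          16     True
3    Th17  0.322472      533          16     True
4     Th2  0.283795      623          16     True
5    Th22  0.277129      554          16     True
6    Th2a  0.300077      559          16     True
7    Treg  0.382286      605          16     True
Th1 -> C00
Th1-17 -> C01
Th17 -> C02
Th22 -> C03
Th2 -> C04
Th2a -> C05
Tfh -> C06
Treg -> C07
```

Each sorted subset is matched by 533–848 cells, every subset's matched
cells concentrate on its true home cluster (the generator's ground truth),
and the per-subset indices around 0.26–0.38 reflect the 0.85-concentrated
cluster programs plus capture noise. The same pipeline runs from the shell:

```bash
tcrtrack simulate --out sim --seed 1
tcrtrack map --bulk-dir sim/bulk \
  --contigs sim/D01_filtered_contig_annotations.csv \
  --contigs sim/D02_filtered_contig_annotations.csv \
  --contigs sim/D03_filtered_contig_annotations.csv \
  --clusters sim/cell_meta.tsv --out mapped --seed 1
```

`mapped/` then holds the subset×cluster count/intensity/size matrices, the
per-subset Shannon table, the per-cell match table with the bulk clonal
frequencies (the dot-plot alpha weights), and run metadata. Other
subcommands: `clonality`, `overlap`, `shared`, `gate`.

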