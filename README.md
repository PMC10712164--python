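# microprot

Growth-rate-resolved analysis of microbial biomass for food applications:
proteome allocation across cellular components, amino-acid profiles,
macromolecular composition, and flow-cytometry-derived cell properties.

## The problem

Microbial biomass (from bacteria such as *Cupriavidus necator* or yeasts
such as *Komagataella phaffii*) is a promising alternative protein source,
but its nutritional quality is not fixed: the growth rate μ and the
availability of carbon and nitrogen substrates reshape the cell. Faster
growth means more ribosomes (and hence more nucleic acid and a shifted
amino-acid profile, since ribosomal proteins are rich in Arg, Lys, Met and
Val), while slow, substrate-limited growth favors higher protein content
and storage-compound (PHA, neutral-lipid) accumulation. `microprot`
implements the computational side of such a study as a reusable, tested
pipeline, together with a synthetic-data generator with known ground truth
so every estimator can be validated offline.

## What it computes

- **Spectral-count quantification** — peptide-spectrum matches (PSMs) are
  resolved to razor proteins by a greedy majority-evidence rule
  (deterministic, lexicographic tie-break), and the per-protein PSM count
  is divided by protein length L_p; the length-normalized count
  q_p = PSM_p / L_p is the quantification value used everywhere.
- **GO cellular-component collapse** — a reference is built from all
  is_a/part_of descendants of *cellular anatomical entity* (GO:0110165),
  *protein-containing complex* (GO:0032991) and *ribosome* (GO:0005840);
  each protein's CC annotations are expanded to their ancestors,
  intersected with the reference, reduced to the most specific term per
  lineage, and collapsed to simplified labels (ribosome, protein
  containing complexes, membrane, or the term name). Per-label razor
  quantification is summed and the top 3 components reported.
- **Amino-acid profiles** — f_a = Σ_p q_p·count_{p,a}, normalized by
  residue count (mol fraction) or by average residue mass
  (g AA/g protein, the default), plus the relative difference
  Δ_a = (f_{a,c} − f_{a,ribo})/f_{a,ribo}·100 % of each component versus
  ribosomal proteins, and the essential + conditionally essential subset.
- **Growth and substrates** — observed growth rate as the
  consecutive-pair log-slope of OD, productivity as ΔCDW/Δt, organic
  substrates aggregated as chemical oxygen demand (COD; 1 eeq = 8 gCOD,
  factors from elemental stoichiometry, e.g. fructose 192/180 gCOD/g),
  and substrate-abundant vs substrate-limiting phase stratification.
- **Correlation analysis** — pairwise Spearman correlograms (mid-rank
  ties, t-approximation p-values, α = 0.05) stratified by phase and
  limitation type, and OLS fits with pointwise 95 % confidence bands.
- **Flow cytometry** — singlet discrimination on the BL1 area/height
  ratio; total/intact/damaged cell concentrations from SYBR Green /
  propidium-iodide panels (events / recorded volume × dilution; 75 µL
  default volume); PHA-positive cells via the SSC → SYTO 62 → BODIPY
  triple-threshold gate; median stain intensities as linear content
  proxies.
- **Synthetic data** — dual-Monod batch growth (carbon, nitrogen or dual
  limitation), proteomes with component-specific amino-acid biases, PSM
  tables following the allocation growth law φ_ribo(μ) = φ0 + k·μ, and
  lognormal-mixture event tables, all reproducible from one seed.

## Worked example

```python
from microprot.synthetic import SimConfig, simulate_proteome, simulate_psm_tables
from microprot.quant import quantify
from microprot.ontology import ReferenceSet, label_proteins, allocate

cfg = SimConfig(seed=1)
prot = simulate_proteome(cfg)
ref = ReferenceSet.build(prot.graph)
labels = label_proteins(prot.annotations, prot.graph, ref)

for mu in (0.10, 0.30):
    table = simulate_psm_tables(cfg, [mu], proteome=prot)[0]
    sq = quantify(table, prot.db)
    alloc = allocate(sq, labels)
    shares = {lab: alloc.label_quant[lab] / sq.total() for lab in alloc.top_k}
    print(f"mu = {mu:.2f} 1/h  top-3:",
          ", ".join(f"{lab} {100*s:.1f}%" for lab, s in shares.items()),
          f" annotated {100*alloc.annotated_fraction:.1f}%")
```

prints

```
mu = 0.10 1/h  top-3: membrane 20.5%, cytoplasm 18.9%, ribosome 15.2%  annotated 59.8%
mu = 0.30 1/h  top-3: ribosome 25.3%, membrane 18.1%, cytoplasm 16.7%  annotated 64.5%
```

At the low rate the membrane is the largest annotated component; at the
high rate ribosomes take over (the generating growth law puts the
ribosomal mass share at 15 % and 25 % at these two rates, and the
pipeline recovers it from Poisson-noisy spectral counts). About 60 % of
the quantification is attributable to an annotated cellular component;
the remainder has no CC annotation. Comparing amino-acid profiles at
μ = 0.20 1/h,

```python
from microprot.aa import profile, rel_diff
table = simulate_psm_tables(cfg, [0.20], proteome=prot)[0]
sq = quantify(table, prot.db)
ribo = profile(sq, prot.db, subset=prot.proteins_of("ribosome"))
cyto = profile(sq, prot.db, subset=prot.proteins_of("cytoplasm"))
print(rel_diff(cyto, ribo).delta_pct[["K", "R", "M", "V", "C", "F"]])
```

shows cytoplasmic proteins depleted in Lys (−34.5 %), Arg (−29.0 %),
Met (−37.0 %) and Val (−35.7 %) and enriched in Cys (+41.2 %) and
Phe (+22.9 %) relative to ribosomal proteins — so a biomass grown faster
(more ribosome-heavy) is relatively richer in Lys/Arg/Met/Val and poorer
in Cys/Phe.

The same workflow is available from the shell:

```bash
microprot simulate --seed 1 --out data/
microprot quantify --psms data/psm_tables.csv --fasta data/proteome.fasta --out quant.tsv
microprot allocate --obo data/ontology.obo --annot data/annotations.tsv --quant quant.tsv --out alloc.tsv
microprot aaprofile --quant quant.tsv --fasta data/proteome.fasta --out profiles.tsv
microprot cytometry --events data/events_SGPI.csv --panel SGPI --bl1-threshold 100 --out cyto.tsv
microprot correlate --series data/series_carbon.csv --out correlograms.tsv
```

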