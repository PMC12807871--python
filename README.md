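# mutscan

Saturation mutational scanning of tiled coding regions: nucleotide-level
variant library design, pooled-amplicon single-mutation counting,
synonymous-normalised enrichment scoring, and integration of activation and
drug-resistance screens into a druggability catalog.

The package is aimed at groups running deep mutational scanning (DMS) of
kinase domains — the motivating system is the FGFR1–4 receptor tyrosine
kinase family, where every possible kinase-domain point mutation can be
assayed in parallel for growth-factor-independent activation and for
resistance to the clinical FGFR inhibitors pemigatinib and futibatinib —
but every stage is generic over any in-frame coding sequence.

## The model

Each 80-codon tile of the target domain is synthesised as a pool of 720
oligos (3 substitutions × 240 nt, flanked by 30 nt of wild-type context,
300 nt total). After selection, paired amplicon reads are merged, assigned
to their tile, and accepted only when they carry exactly one substitution
relative to the 260-nt wild-type reference. For variant *i* in selection
replicate *s* with plasmid-baseline replicates *b*:

```
f_i       = (c_i + α) / Σ_j (c_j + α)                    within-sample frequency (α = 0.5)
r_i(s)    = f_i(s) / median_b f_i(b)                     baseline-normalised ratio
E_i(s)    = r_i(s) / median_{j ∈ synonymous} r_j(s)      enrichment score
```

so synonymous (neutral) variants have median enrichment 1 by construction.
A variant is called a **hit** when its median enrichment across replicates
is ≥ 1.5 *and* at least 3 of 4 (activation) or 2 of 3 (resistance)
replicates individually reach 1.5; hits are tiered at median 1.5–2.5
(potential), >2.5–5 (weak), >5–10 (moderate) and >10 (strong).
Loss of function mirrors the rule at median ≤ 0.4. Significance per
variant is a two-tailed t-test of log enrichments against the pooled
synonymous replicates (F-test-selected equal-variance or Welch form),
corrected with the two-stage step-up FDR procedure of Benjamini, Krieger &
Yekutieli at Q = 1%. Assay-level clinical evidence strength is calibrated
with OddsPath = [P2(1−P1)] / [(1−P2)P1] against labelled
pathogenic/benign controls, mapped to ACMG PS3/BS3 tiers.

Integrating the three screens assigns every variant one of seven phenotype
groups (the non-empty combinations of activating / pemigatinib-resistant /
futibatinib-resistant); a variant is *druggable* when it is activating and
sensitive to at least one inhibitor.

## Worked example

Design a library for a synthetic 120-codon gene whose domain spans codons
11–90, simulate a ground-truthed screen, score and classify it:

```python
import numpy as np
from mutscan import library_design as ld, read_calling as rc
from mutscan import simulate as sim, pipeline

rng = np.random.default_rng(1234)
cds = sim.random_cds(120, rng)
model = ld.make_gene_model("geneA", cds, (11, 90))
tiles, designs = ld.design_library(model)
print(len(designs), len(designs[0].oligo_sequence))   # 720 300

frame = ld.designs_to_frame(designs)
ref = rc.TileReference.from_tile(tiles[0])
config = sim.SimConfig(seed=20, depth=300, error_rate=0.005)
res = pipeline.run_synthetic_fastq_pipeline(frame, ref, config, "scratch/e2e")
print(res["recovery"].to_string(index=False))
```

which prints the 720-oligo / 300-nt design check and a recovery report like

```
    screen        bin   n  n_called  rate              metric
activation    neutral 670         0   0.0 false_positive_rate
activation  [1.5,5.0)   4         4   1.0         sensitivity
activation [5.0,10.0)  19        19   1.0         sensitivity
activation [10.0,inf)   2         2   1.0         sensitivity
activation        >=5  21        21   1.0         sensitivity
       pem    neutral 695         0   0.0 false_positive_rate
       pem  [1.5,5.0)   7         7   1.0         sensitivity
       pem [5.0,10.0)  13        13   1.0         sensitivity
       pem [10.0,inf)   5         5   1.0         sensitivity
       pem        >=5  18        18   1.0         sensitivity
```

i.e. at 300 reads per variant every programmed effect ≥ 5-fold is
recovered as a hit and no truly neutral variant is called.

The same stages are exposed on the command line:

```bash
mutscan design --cds gene.fasta --domain 11-90 --out lib
mutscan simulate --design lib.manifest.tsv --seed 42 --depth 300 --out simdir
mutscan score --counts simdir/counts.tsv --design lib.manifest.tsv \
    --plasmid plasmid_1,plasmid_2,plasmid_3 --selection act_1,act_2,act_3,act_4 \
    --out act_scores.tsv
mutscan classify --scores act_scores.tsv --design lib.manifest.tsv \
    --screen activation --out act_calls.tsv
mutscan integrate --act act_calls.tsv --pem pem_calls.tsv --fut fut_calls.tsv \
    --design lib.manifest.tsv --out catalog.tsv
```

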