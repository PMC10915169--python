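# ribodyn

Codon-resolution analysis of ribosome-profiling data:

- **profiles** — read/validate CDS FASTA and per-nucleotide footprint
  tracks (simple TSV dialect), replicate averaging, gene filtering,
  codon densities, pause scores, and model-ready (sequence window,
  reference-density window, target) datasets with deterministic
  fraction/k-fold splits.
- **nn** — a two-branch regression model (codon-sequence branch +
  log reference-density branch; convolution blocks, multi-head
  self-attention, feed-forward stage, element-wise merge, ReLU head)
  implemented in pure NumPy with hand-written backprop, trained with
  Adam, cosine learning-rate decay and early stopping. Checkpoints
  round-trip bit-exactly.
- **analysis** — translation efficiency, positional codon enrichment,
  Fisher-exact differential pause-site detection (p < 0.001, OR > 1),
  in silico mutagenesis sequence impact scores (SIS), K-means SIS
  clustering with automatic elbow selection, per-cluster codon
  enrichment matrices, and a pluggable folding-energy interface
  (external RNAfold or a deterministic stub).
- **simulate** — a fully seeded synthetic generator: genes with known
  codon dwell times and context (stall) effects, Poisson/multinomial
  read allocation, a protocol-bias operator that redistributes reads
  within genes, and a collision (disome-like) track derivation.

Counts are assumed already assigned to a single ribosome-site position
per footprint; read alignment and A/P-site offset calibration are out of
scope. Coordinates are 0-based nucleotide positions within the CDS.

## CLI

```bash
# synthetic genome + paired tracks (bit-reproducible given --seed)
ribodyn simulate --seed 7 --n-genes 100 --bias "TCT:3.0,TCC:3.0" -o sim/

# filtering, codon densities, pause scores
ribodyn preprocess --cds sim/genes.fasta --ref-profile sim/profile.tsv \
    --organism prok -o prep/

# train the density model (reference -> target condition)
ribodyn train --cds sim/genes.fasta --ref-profile sim/profile_biased.tsv \
    --target-profile sim/profile.tsv --window 10 --seed 0 -o run/

# predictions, differential pause sites, SIS, clustering
ribodyn predict --model run/model --cds sim/genes.fasta \
    --ref-profile sim/profile_biased.tsv -o pred/
ribodyn pause-sites --cds sim/genes.fasta --ref-profile sim/profile.tsv \
    --target-profile sim/profile_biased.tsv --alpha 0.001 -o sites/
ribodyn sis --model run/model --cds sim/genes.fasta \
    --ref-profile sim/profile_biased.tsv --sites sites/pause_sites.tsv -o sis/
ribodyn cluster --sis sis/sis.tsv -o clusters/
```

Every subcommand writes a `manifest.json` (resolved configuration,
package version, input SHA-256) sufficient to replay the run; a flat
YAML config can pre-set any flag (`--config run.yaml`), with explicit
flags taking precedence.

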