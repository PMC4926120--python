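# barcodiag

DNA-barcode diagnostics for closely related species, built around the
workflow used to identify stored-product pest insects (flour beetles of
the genus *Tribolium*) from the standard 658-bp COI barcode:

* **Library analysis** — Kimura 2-parameter (K2P) pairwise distances,
  per-species intra/inter divergence tables, base composition, haplotype
  collapsing, neighbour-joining trees with bootstrap support, and
  nearest-neighbour classification of unknown specimens.
* **Species delimitation** — automatic barcode-gap discovery: find the gap
  between the intra- and inter-specific distance modes above a prior
  divergence limit and partition the library by single linkage,
  recursively.
* **Assay design** — species-specific endpoint-PCR primers and TaqMan
  probe/primer sets anchored on diagnostic bases (columns fixed in the
  target species and absent from all others), each candidate scored
  against explicit rule lists (length, GC, structure dG, 3'-end
  specificity, false priming, Tm window; probe- and qPCR-specific rules),
  with nearest-neighbour thermodynamics throughout.
* **In-silico validation** — mismatch-tolerant binding-site search,
  amplicon prediction, and a species x primer-pair specificity grid
  rendered as a plain-text "virtual gel".

The K2P distance between two aligned sequences with transition proportion
`P` and transversion proportion `Q` is

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

and a library shows a *barcode gap* when the distribution of intraspecific
distances (here <= ~2%) is separated from the interspecific one (>= ~16%).
A primer is species-specific when its 3' end covers a diagnostic base, so
extension fails on every non-target species.

The package ships the published reference assays for the six beetle
species (`reference_specific_primers()`, `reference_taqman_sets()`), whose
names encode their binding coordinates (`Tde25F20` = forward, binds
25–44): the product of a pair is `rev_start + rev_len - fwd_start`. A
seeded simulator (`barcodiag.fixtures`) generates barcode libraries with
planted diagnostic windows and ground truth, so the whole pipeline is
testable without any downloads.

## Worked example

```python
import barcodiag as b
from barcodiag.fixtures import SimSpec, simulate_library

lib = simulate_library(SimSpec(seed=1))          # 6 species x 4 seqs x 658 bp
m = b.pairwise_matrix(lib.alignment)             # K2P matrix
print(b.divergence_summary(m, lib.species_of).to_tsv())

part = b.abgd_partition(m, prior=0.0046)         # gap partition at prior 0.46%
print("groups:", part.n_groups)

designs = b.design_assay(lib.alignment, lib.species_of, target="sp03")
best = designs[0]
print("best pair:", best.forward.name, "/", best.reverse.name,
      "product", best.product_length)
grid = b.specificity_matrix([best], lib.alignment, lib.species_of)
print(grid.virtual_gel())
```

prints

```
        intra_avg  intra_min  intra_max  inter_avg  inter_min  inter_max
sp01    0.53       0.3        0.76       19.16      17.98      19.98
...
All     0.64       0.3        0.92       19.44      17.98      20.52

groups: 6
best pair: s85F18 / s561R19 product 495
species  s85F18+s561R19
sp01                  -
sp02                  -
sp03     495,495,495,495
sp04                  -
sp05                  -
sp06                  -
```

The divergence table shows the barcode gap (intra max 0.92% vs inter min
17.98%), the partition recovers the six generating species at a 0.46%
prior, and the designed pair amplifies all four target sequences (one
495-bp band) and nothing else — a diagonal "gel".

A command-line interface mirrors the library
(`barcodiag dist|summary|haplo|nj|gap|classify|design|ispcr|simulate`);
run `barcodiag --help`.

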