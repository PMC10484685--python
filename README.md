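# fourbase

Analysis toolkit for **four-base DMS-MaP** RNA structure probing.

Dimethyl sulfate (DMS) methylates the Watson-Crick face of unpaired A, C,
G and U nucleobases, and mutational profiling (MaP) reverse transcription
encodes those adducts as mutations readable by sequencing. Guanine is the
hard case: DMS predominantly methylates G at N7, independently of base
pairing, and reverse transcriptases read a small fraction of those
N7-methyl adducts through as G→A mismatches — burying the rare,
structurally informative N1-methyl signal. The decisive observation is
that the two adducts leave distinct mutational signatures: N7-G is decoded
almost exclusively as G→A, while N1-G is decoded as G→C and G→T. Dropping
G→A mismatches, G-containing multi-nucleotide mismatches, and all indels
("no data", not "unmutated") turns G into a useful probe and makes DMS a
single-reagent, all-four-base structure probe.

`fourbase` implements the computational stack downstream of alignment:

| module | what it does |
| --- | --- |
| `fourbase.mutation_data` | parse per-read mutation records, apply the mutation-signature filter, accumulate per-position counts and mutation spectra |
| `fourbase.reactivity` | background-subtracted modification rates and nucleotide-specific normalization `N_n = max{⟨r_n⟩_[P90,P95], P75(r_n > 0.001)}`; `.dms` output |
| `fourbase.infometrics` | AUROC against a known structure; double-gamma-mixture reactivity likelihoods; per-position structural information `SI(r) = 1 − H(s|r)` with `p(b|r) = p̂(r|b)/(p̂(r|b)+p̂(r|u))`, and its molecule average ESI (bits) |
| `fourbase.pairmap` | single-molecule PAIR analysis: 2×2 co-modification contingency per 3-nt window pair, G-test with Bonferroni correction, co-modification cutoff n11 ≥ 10, complementarity and reactivity gates (minor ≥ 0.2, principal ≥ 0.4 + mutual-best) |
| `fourbase.pseudoenergy` | fit paired/unpaired reactivity likelihoods and emit a dists-style folding-potential table |
| `fourbase.structure_io` | CT / dot-bracket parsing (pseudoknots supported) and ppv/sens structure comparison with one-position register shifts, singleton-pair removal |
| `fourbase.simdata` | synthetic read generator with per-event ground truth: Bernoulli adducts conditioned on pairing status, N7-G read-through, mutation-type multinomials, background errors, multi-state ensembles |
| `fourbase.cli` | `fourbase` command with `simulate`, `profile`, `esi`, `pairmap`, `potentials`, `evaluate` subcommands |

## Worked example

Simulate a probing experiment on the built-in 149-nt toy RNA with an
8-bp helix melted in half the molecules, build a normalized profile, and
run PAIR analysis:

```bash
fourbase simulate --n 300000 --seed 7 --melt 4-11 --out sim/
fourbase profile --treated sim/parsed.tsv --fasta sim/target.fa \
    --min-depth 1000 --out sim/toy.dms
fourbase pairmap --reads sim/parsed.tsv --profile sim/toy.dms \
    --fasta sim/target.fa --out sim/pairs.tsv
```

which reports on stderr:

```
wrote 300000 reads to sim/parsed.tsv
wrote profile to sim/toy.dms
reported 3 PAIRs to sim/pairs.tsv
```

and `sim/pairs.tsv` contains exactly the melting helix, tiled in
register by principal PAIRs:

```
i	j	n11	depth	g_stat	corrected_p	pair_class	reason
5	22	246	296472	30.5901	0.00016041365209226743	principal
6	21	237	293346	42.0683	4.436122902138079e-07	principal
8	19	191	290393	25.7363	0.0019699117706105805	principal
```

(windows 5–7/22–24, 6–8/21–23 and 8–10/19–21 are the antiparallel
3-mers of the planted helix (4,25)…(11,18)). Without `--melt`, the same
pipeline reports 0 PAIRs — modifications are then independent across
molecules and the G-test stays at its null calibration. `sim/toy.dms`
holds one line per position (`position  base  reactivity`, no-data
sentinel −999): unpaired A/C positions normalize to reactivities near 1,
paired positions near 0.1, with G and U on the same common scale thanks
to the per-nucleotide normalization factors.

The per-nucleotide profile side in Python:

```python
import fourbase as fb

struct = fb.default_toy_structure()
params = fb.SimParams(structures=[struct])          # paper-scale chemistry
reads, truth = fb.simulate_reads(params, 100_000, seed=7)

counts = fb.count_profile(reads, struct.sequence, mode="dms")
profile = fb.normalize(fb.modification_rate(counts))
a = fb.auroc(profile.reactivity, ~struct.is_paired(), profile.mask)
print(f"AUROC {a:.3f}")                             # AUROC 1.000 at this depth
```

The equivalent run with `mode="unfiltered"` (traditional DMS-MaP) leaves
the G→A noise in place and drops the G-nucleotide AUROC to 0.68 on this
run — the with/without-filter contrast is one flag apart throughout the
package.

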