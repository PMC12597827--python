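# cardioniche

Spatially informed cell-state niche analysis for developmental tissue
atlases, modelled on the analysis chain used to chart the early human heart
(postconceptional weeks 5.5–14): spatial transcriptomic spots are
deconvolved into cell-state proportions against a single-cell reference,
recurring cellular niches are discovered as the graph of strongly
co-detected state pairs, in situ sequencing (ISS) signals are decoded into
quality-filtered gene calls, and enzyme/receptor surrogate pairs score
directed ligand–receptor interactions (e.g. TH→ADRB1 for adrenergic
innervation of the sinoatrial node).

It is aimed at computational biologists who want the niche-discovery logic
as a tested, reusable pipeline. Because the primary atlas data are
access-controlled, a synthetic-data module generates single-cell
references, spatially structured spot sections and ISS tensors with full
ground truth, so the whole chain runs — and is validated — end to end on a
laptop.

## The method

1. **State profiles.** Labelled single-cell counts are library-size
   normalized (counts-per-10⁴, log1p); each state k gets a mean expression
   profile and a fraction-expressing vector.
2. **Deconvolution.** Each spot's expression y is modelled as a
   non-negative mixture of state profiles: minimize ‖y − Xβ‖₂ subject to
   β ≥ 0 (NNLS), then normalize β to the simplex to get proportions θ.
3. **Co-detection.** For states a, b the co-detection score is the Pearson
   correlation r(θ·ₐ, θ·ᵦ) over spots (per section, then spot-count
   weighted). The niche graph keeps edges with r > 0.07 (strict); connected
   groups of states are niches. Stability is checked across three
   developmental age groups (5.5–6, 7–8, 9–14 PCW).
4. **ISS decoding.** Per round, the winning channel is the intensity
   argmax; quality q_r = I_max/ΣI. Calls need an exact codebook match and
   minimum per-round quality strictly over 0.4.
5. **Ligand–receptor surrogate score.** For a (sender, receiver) state pair
   and an enzyme→receptor surrogate pair, score = (μ_enzyme,sender +
   μ_receptor,receiver)/2, gated to 0 unless ≥10% of cells on each side
   express the gene.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Run the full synthetic study through the numbered drivers:

```bash
python analysis/01_simulate.py --seed 0     # reference, sections, ISS run
python analysis/02_build_profiles.py
python analysis/03_deconvolve.py
python analysis/04_codetect_niches.py
python analysis/05_decode_iss.py
python analysis/06_score_lr.py
```

Output (seed 0):

```
reference: 600 cells x 200 genes, 6 states (10 markers each)
sections: 4 x 400 spots (3 contiguous niches), PCW [5.5, 7.5, 10.0, 13.0]
...
section_0 (PCW 5.5): 400/400 spots fitted, mean per-spot L1 error vs truth = 0.0364
...
niche graph at score > 0.07: 6 states, 3 edges
  niche 0: state_0, state_3
  niche 1: state_1, state_4
  niche 2: state_2, state_5
age-group stability (score correlation / edge Jaccard):
  5.5-6 vs 7-8: r = 0.999, J = 1.00
...
decoded 5000 spots; retained 5000 (min quality > 0.4)
call accuracy: 100.00% unfiltered, 100.00% after the quality filter
top interaction: state_0 -> state_5 (score 6.236); planted pair is state_0 -> state_5
```

Reading this: deconvolution recovers each spot's planted composition to
~0.04 L1 under Poisson noise; the three planted two-state niches emerge as
exactly the three connected components of the co-detection graph; the score
matrix is essentially identical across age groups simulated from one truth
(r ≈ 1, Jaccard 1); low-background ISS decoding is error-free; and the
planted enzyme→receptor pair tops the interaction ranking.

The same chain is available as one command with a YAML config
(`cardioniche run --config cfg.yaml --out DIR --seed N`), or stage by stage
via the `simulate`, `profiles`, `deconvolve`, `codetect`, `decode` and
`lrscore` subcommands.

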