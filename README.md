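# affcom

A communication-theoretic model of multimodal affordance perception for
computational cognitive scientists interested in whether perception of
action possibilities can be "direct" or must involve integration of sensory
channels.

The model represents an affordance landscape as an m×n matrix **A** whose
axes are two ambient energy arrays (e.g. light and sound).  Each axis is
read by a capacity-limited encoder that can emit only L = 2^R distinct
signals; a shared conditional-expectation decoder reconstructs affordance
values from signal pairs, so the pipeline is the Markov chain
A ↦ O ↦ Z ↦ Â with distortion L_MSE(A, Â) = (1/|O|) Σ (a_bc − â_bc)².

Two encoding strategies are compared:

- **direct** — each encoder maximizes affordance information about its own
  axis (arg max I(A^B; Â^B), optimized per axis via its MSE surrogate);
- **indirect** — the encoder pair jointly minimizes the full-matrix
  reconstruction error, which amounts to relaying sensory information
  (arg max I(O^B; Ô^B)) for downstream integration.

Whether indirect encoding wins is governed by the *synergy* the two axes
carry about the affordance, quantified by partial information
decomposition:

    I_syn({Z^B, Z^C}; A) = I(Z^B, Z^C; A) − I_union({Z^B, Z^C}; A)

where the union information minimizes I*(Z^B,Z^C; A) over all joints
preserving both (Z_i, A) pairwise marginals — computed here by an in-package
convex solver with a brute-force oracle, alongside the WholeMinusSum and
Smax bracketing bounds and a distance-weighted (spatial) entropy of the
sensory estimates.  Encoders are optimized by seeded stochastic hill
climbing with random restarts, certified against exhaustive enumeration on
small instances.

## Worked example

The package ships the 4×4 synergistic toy landscape

```
0 0 1 1
0 0 2 1
1 2 0 0
1 1 0 0
```

with observation axes 1..4 and 1-bit encoders (L = 2).  The direct coding
maps {1,4}→0, {2,3}→1 on both axes; the indirect coding maps {1,2}→0,
{3,4}→1.  Running

```sh
affcom toy
```

prints

```
   direct: (0.44, 0.25, 0.0, 0.0, 1.0, 1.0)
 indirect: (0.09, 1.0, 1.0, 1.0, 0.0, 0.0)
{
  "hill_climb_direct_B": 0.0,
  "hill_climb_direct_C": 0.0,
  "hill_climb_indirect": 0.09375,
  "exhaustive_direct": 0.0,
  "exhaustive_indirect": 0.09375
}
```

Each row lists (L_MSE(A,Â), I_syn({Z^B,Z^C};A), I(O^B;Ô^B), I(O^C;Ô^C),
I(A^B;Â^B), I(A^C;Â^C)).  The direct coding reconstructs each axis's mean
affordance profile perfectly (I(A^B;Â^B) = 1) but collapses every sensory
state to the single estimate 2.5 (I(O^B;Ô^B) = 0) and pays for it with
affordance distortion 0.44 while capturing only 0.25 bits of synergy.  The
indirect coding preserves a full bit of sensory information per axis
(estimates 1.5/3.5), captures all 1 bit of synergy, and more than halves
the distortion (0.09 = 3/32).  The trailing block shows that hill climbing
re-derives both codings and that exhaustive enumeration certifies them as
global optima.

The same comparison at scale, on synthetic 32×32 "standing figure" blob
landscapes quantized to 5 levels with 3-bit encoders:

```sh
affcom synth --kind blobs --m 32 --n 32 --levels 5 --seed 7 -o A.csv
affcom optimize --landscape A.csv --strategy indirect \
    --signals-b 8 --signals-c 8 --runs 20 --seed 7
```

or as a full seeded batch with paired statistics (JSON config with the
fields of `ExperimentConfig`):

```sh
affcom experiment --config cfg.json -o outdir --plots
```

Library use mirrors the CLI: `toy_landscape()`, `build_decoder`,
`metrics_report`, `optimize_direct` / `optimize_indirect`, `synergy`,
`run_batch`.

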