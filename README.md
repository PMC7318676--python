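# transglyc

Equilibrium yield prediction, reaction design and constant fitting for
nucleoside-phosphorylase-catalyzed transglycosylations.

Enzymatic transglycosylation is the protecting-group-free way to make
nucleosides and nucleoside analogues: a phosphorylase cleaves a cheap sugar
donor (uridine, thymidine) with phosphate into a pentose-1-phosphate, which
glycosylates a free nucleobase to give the product nucleoside. Yields of
these one-pot reactions are fixed by thermodynamics, not by enzyme amount —
by the apparent equilibrium constants of phosphorolysis of the donor (K1)
and of the product (K2):

    K1 = [B1][P1P] / ([N1][P])        K2 = [B2][P1P] / ([N2][P])

Their ratio K_N = K1/K2 sets the maximum (ideal) yield via the net reaction
N1 + B2 ⇌ B1 + N2, solvable in closed form; any phosphate actually present
at equilibrium diminishes the yield by sequestering sugar as
pentose-1-phosphate and phosphorolyzing product — an effect governed by K2,
so two systems with the same K_N can respond very differently to phosphate.

`transglyc` is for practitioners planning such syntheses: it predicts yields
(ideal and at finite phosphate, via a full six-species equilibrium solver
with exact mass balance), inverts the model for design (how much donor
excess for a target yield; how much phosphate before losing more than an
acceptable number of percentage points), and fits (K1, K2) from endpoint
yield measurements with bootstrap confidence intervals. See
`docs/methods.md` for the model and numerics.

## Worked example

Uridine donor (K1 = 0.16 at 60 °C, pH 9), 1 mM, glycosylating 0.5 mM of a
nucleobase. For adenine (product adenosine, K2 = 0.01, so K_N = 16):

```
$ transglyc predict --kn 16 --donor-mM 1 --base-mM 0.5
ideal N2 = 0.473401 mM
ideal yield = 94.68 %
```

Of the 0.5 mM base, 94.7 % ends up glycosylated in the vanishing-phosphate
limit — a high-K_N pairing needs only a twofold donor excess for an
excellent yield. Contrast 5-ethynyluracil (product 5-ethynyluridine,
K2 = 0.35) with 10 equivalents of phosphate in the pot:

```
$ transglyc solve --k1 0.16 --k2 0.35 --donor-mM 1 --base-mM 0.5 --phosphate-equiv 10
N1 = 0.400403 mM
B1 = 0.599597 mM
N2 = 0.116939 mM
B2 = 0.383061 mM
P = 4.51734 mM
P1P = 0.482659 mM
yield = 23.39 %
```

The ideal yield for this pairing is 54.8 %, so excess phosphate costs over
30 percentage points: nearly half a millimolar of sugar sits trapped as
pentose-1-phosphate, and the high product constant K2 keeps phosphorolyzing
the nucleoside of interest. Asking the design inverter how much phosphate
this reaction tolerates before losing 4 percentage points:

```
$ transglyc design --k1 0.16 --k2 0.35 --donor-mM 1 --base-mM 0.5 --max-gap 4
max phosphate = 0.200001 mM (0.4 equiv)
```

Keep phosphate at or below ~0.4 equivalents of the base and the yield stays
within 4 points of ideal. The same operations are available as library
functions (`ideal_yield`, `solve_equilibrium`, `yield_vs_phosphate`,
`phosphate_gap`, `donor_for_target_yield`, `max_phosphate_for_deviation`,
`yield_landscape`, `fit_constants`, `bootstrap_confidence`,
`simulate_measurements`); the CLI also offers `sensitivity`, `landscape`,
`fit` and `simulate` subcommands, YAML reaction configs (`--config`) and
CSV/JSON output (`--out`, `--format`).

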