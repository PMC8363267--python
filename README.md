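# synerk

Stochastic modelling of the signalling pathways that activate ERK during
induction of late-phase long-term potentiation (L-LTP).

Synaptic stimulation recruits ERK (extracellular signal-regulated kinase)
through several convergent routes: calcium acting through the
calcium–calmodulin-activated GEF RasGRF and through CaMKII's control of the
synaptic GAP SynGap, and cAMP acting through Epac, PKA and the Giβγ-recruited
Src route.  Which routes dominate depends on the *temporal pattern* of
stimulation — massed versus spaced 100 Hz trains — and on whether the
pathways combine additively or synergistically.  `synerk` is a library for
asking exactly those questions of a single-compartment mass-action model:
it simulates the network stochastically (exactly or with adaptive
tau-leaping) or deterministically, drives it with the standard induction
protocols, and quantifies the outcome with the field's statistics.

The model is a reaction network evolving by mass action in one well-mixed
volume V, with molecule counts n = c·N_A·V.  Stochastic paths follow the
chemical master equation via Gillespie's direct method, accelerated by
adaptive tau-leaping with leap length τ chosen so each propensity changes
by less than a tolerance ε = 0.1 per leap; the deterministic limit
dc/dt = S·v(c) serves as the oracle.  Activity is summarised as area under
the curve (AUC) above the pre-stimulus baseline; dose–response curves are
classified linear versus non-linear by comparing a line, a logarithm and a
Hill function max·xⁿ/(xⁿ + hⁿ) using adjusted R² and AIC; synergy is
tested by two-way ANCOVA of AUC against the stimulation covariate and a
combination-versus-summation factor; and robustness to ±10% parameter
variation is ranked by random-forest importances.

The repository ships a reduced fixture network (13 species, 18 reactions)
with the full model's structural motifs — an ultrasensitive,
phosphatase-controlled kinase switch for calcium, a linear cAMP→GEF→GTPase
branch, and branch competition for a shared GTPase pool — so the entire
pipeline is testable end to end.  The published parameterisation loads
through the same tabular interface (`load_network`).

## Worked example

Classify the ppERK dose–response for each input
(`examples/03_dose_response_classification.py`):

```
cAMP duration scan (0.5 µM):
  x          auc
  1  2797.758223
  4  3196.450461
 10  3864.018955
 30  5752.839777
100 12045.596698
classification: linear (linear adjusted R^2 = 0.998)

calcium duration scan (0.5 µM):
classification: non-linear
Hill half-point = 5.54 s (duration threshold), n = 30.5
```

Total ppERK grows in proportion to cAMP exposure (a line explains 99.8% of
the variance), while calcium shows a thresholded, switch-like response: a
0.5 µM pulse shorter than ~5.5 s barely engages ERK, and a longer one flips
the autophosphorylating kinase switch and saturates the response.  Testing
whether the two cAMP-side branches add (`examples/04_synergy_ancova.py`):

```
  x  auc_combo  auc_sum
  1     6396.0   8414.0
  4     6837.0   9213.0
 10     7629.0  10618.0
 30    10085.0  14809.0
100    18582.0  29050.0

ANCOVA: F = 60.3, df = (2, 7)
  stimulation (duration): t = 10.30, p = 1.8e-05
  type (combo vs sum):    t = -3.82, p = 0.0065
verdict: sublinear
```

The combined response falls short of the sum of the single-branch
responses at every duration — both branches load the same GTPase pool, and
the significant negative type effect quantifies that competition.  The
other examples cover network construction and knockouts, stochastic versus
deterministic propagation, the massed/spaced L-LTP interval scans, and the
robustness forest.

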