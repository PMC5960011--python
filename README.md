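# bellcog

Analysis tooling for bipartite two-outcome coincidence experiments in
quantum cognition — concretely, the windrose experiment in which
respondents pick a pair of compass directions as a good example of the
combined concept *Two Different Wind Directions*.  Four joint
measurements AB, AB′, A′B, A′B′ are built from two antipodal-axis
measurements per conceptual sub-system (A = N/S, A′ = E/W, B = NE/SW,
B′ = SE/NW); the data object is the 4-block joint-probability table
p(X_i, Y_j).

On such tables the package computes and models:

* **CHSH statistic** S = E(A,B) − E(A,B′) + E(A′,B) + E(A′,B′), where
  E(X,Y) = p11 − p12 − p21 + p22.  |S| ≤ 2 for experimentally separated
  sub-systems; 2√2 is the Tsirelson bound of quantum product
  measurements; 4 is the algebraic maximum.
* **Marginal-law (no-signaling) residuals** — the eight differences
  between one sub-system's outcome marginals under the two possible
  partner measurements.
* **Rotation symmetrization** — the coin (180°) and octahedral-die
  (eight 45° steps) protocols that mix rotated replicas of the whole
  configuration under the consistency assumption (a respondent keeps the
  same unordered direction pair in every rotated configuration).  The
  mix restores every marginal to ½ exactly while preserving S exactly.
* **Singlet quantum model** — state (|12⟩ − |21⟩)/√2 with product spin
  observables (σ·a)⊗(σ·b); Born probabilities ¼(1 − s_L s_R a·b) in
  closed form and by explicit C⁴ computation, plus a solver recovering
  measurement directions from a symmetric table.
* **Rigid-rod mechanical model** — two spheres with (ε, d)-elastic
  band measurements, entangled by a rigid rod: closed-form sequential /
  order-mixed probabilities, E = −cosθ/ε + d²/ε²,
  |S| = 2|√2/ε − d²/ε²|, and a mechanistic Monte-Carlo simulator.  It
  dissociates the two violations: symmetric bands (d = 0) preserve the
  marginal law with |S| up to 4, while asymmetry violates the marginal
  law and *reduces* |S|.
* **Synthetic respondents** — categorical sampling of per-participant
  choices (n = 85 by default), stochastic versions of both mixing
  protocols, and a percentile bootstrap over participants.

## Worked example

The raw experimental table ships as a fixture:

```sh
$ bellcog chsh --in src/bellcog/data/wind_eq2.csv
E(AB) = -0.60
E(ABp) = +0.64
E(ApB) = -0.60
E(ApBp) = -0.64
S = -2.4800  |S| = 2.4800  (minus term on ABp)
CHSH bound |S| <= 2 violated
```

|S| = 2.48 is far above the classical bound 2 — but the raw data also
violate the marginal law (`bellcog marginals --in ...` shows residuals
up to ±0.17), so no quantum model with product measurements fits them.
Symmetrizing with the octahedral-die protocol and fitting the singlet
model:

```sh
$ bellcog symmetrize --in src/bellcog/data/wind_eq2.csv \
    --protocol octahedral --out oct.json
$ bellcog fit-quantum --in oct.json
a: theta = 0.00 deg, phi = 0.00 deg
b: theta = 51.68 deg, phi = 0.00 deg
ap: theta = 76.63 deg, phi = 51.36 deg
bp: theta = 128.32 deg, phi = 51.36 deg
residual = 5.55e-17 (closed-form)
```

The symmetrized table keeps |S| = 2.48 but now obeys the marginal law
exactly, and is reproduced to machine precision by a singlet state with
the four Stern-Gerlach directions above: b at 51.68° from a
(cos 51.68° = 0.62, so p(A₁,B₁) = ¼(1 − 0.62) = 0.095), with a′ and b′
lifted out of the a–b plane by the shared azimuth 51.36°.

`bellcog run --in ... --out report.json` performs the whole chain
(validate → summarize → both symmetrizations → quantum fit) in one
command; `bellcog rod-sim` and `bellcog simulate` drive the rigid-rod
Monte Carlo and the synthetic-respondent sampler.  The same operations
are available as library functions (`bellcog.summarize`,
`bellcog.symmetrize_octahedral`, `bellcog.solve_directions`,
`bellcog.simulate_rod`, `bellcog.sample_mixed_protocol`, ...).

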