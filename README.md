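# ventnet

Simulation of mechanical ventilation of an initially flooded, collapsed
peripheral airway network — for researchers in respiratory biomechanics who
want to study recruitment dynamics, avalanche signatures and
ventilation-induced stress under prescribed-tidal-volume protocols.

In respiratory distress (surfactant-deficient neonates, ARDS), peripheral
airways flood with liquid and collapse under surface tension; ventilation
must force them open ("recruit" them) before gas exchange can resume.
`ventnet` couples reduced-order single-airway reopening mechanics to a
stochastic bifurcating tree through one global airway pressure:

* **Tube law.** Each airway obeys a Lambert-type elastic pressure–area law
  `P = F(a)`: with `α = a/A_max`, `α = α₀(1 − P/P₁)^(−n₁)` when `P ≤ 0` and
  `α = 1 − (1 − α₀)(1 − P/P₂)^(−n₂)` when `P > 0`, with per-generation
  constants for generations 0–16 of the human lung. Wall stiffness is
  `Γ = dF/da`. Heterogeneity enters through one per-airway parameter `λ`
  (unit-mean Gaussian, s.d. `d`, truncated positive) that rescales `A_max`,
  simultaneously setting maximal extension, equilibrium area `a_eq = α₀A_max`
  and stiffness (`Γ ∝ 1/λ`).
* **Reopening.** An airway collapsed to `a_init = C·a_eq` recruits by
  peeling once the airway pressure exceeds its yield pressure
  `P_c = β F(a_init) + c_y P₁ λ^(−1/2)`; above yield the tip advances at
  `U = (m₀/μ) r_eq (P − P_c) λ^(−q)`. The maximal liquid pressure gradient
  across the advancing tip, `G = (P − F(a_init) + 2γ/r_c)/(w r_c)` (per µm),
  is recorded per airway as a proxy for epithelial damage.
* **Network.** One generation-11 subtree: 63 airways over generations 11–16,
  dichotomously branching, with a compliant acinus behind each of the 32
  terminal airways (`V(P) = V_A(1 − e^{−K_A(P−P_A)})` above the acinar
  opening pressure `P_A`). Generations 0–10 form an always-open proximal
  compliance compartment.
* **Engine.** Air is delivered at constant flow `Q = V_T·M/(2048·T_Q)`; at
  every instant the single airway pressure is the root of the
  volume-conservation equation (opened segments at tube-law area + open
  acini + proximal compartment = delivered volume), solved to a residual
  below 10⁻⁹ cm³. Recruitment halts in any airway when `P` falls below its
  yield and resumes when it rises above it again — this feedback produces
  recruitment *avalanches* with transient pressure drops.

## Worked example

```python
from ventnet import (build_network, simulate, damage_report, CM_H2O)

net = build_network(d=0.2, C=0.1, seed=1)   # 63 airways, 32 acini
res = simulate(net)                         # V_T = 10 ml/kg over 2.5 s, no PEEP
rep = damage_report(res)
print(f"initial pressure      : {res.P_init / CM_H2O:.3f} cm H2O")
print(f"full recruitment t_R  : {res.t_recruit_all * 1e3:.1f} ms")
print(f"first passage         : {res.t_first_passage * 1e3:.1f} ms")
print(f"acini open at end     : {int(res.acini['opened'].sum())} / 32")
print(f"end-inflation pressure: {res.trace['P_cmH2O'].iloc[-1]:.2f} cm H2O")
print(f"peak tip gradient     : {rep.G_net:.0f} dyn cm^-2 um^-1")
```

prints

```
initial pressure      : 0.822 cm H2O
full recruitment t_R  : 25.0 ms
first passage         : 8.7 ms
acini open at end     : 32 / 32
end-inflation pressure: 2.97 cm H2O
peak tip gradient     : 10465 dyn cm^-2 um^-1
```

Read: with modest heterogeneity (d = 0.2) and strong collapse (C = 0.1), the
inflation starts at the constant-speed recruitment pressure (0.822 cm H₂O),
the whole tree opens in a single ~25 ms avalanche (first open path to an
acinus after 8.7 ms), and the pressure then climbs past the 2 cm H₂O acinar
opening pressure so all 32 acini ventilate. The largest tip stresses occur
in the narrowest, most peripheral airways (generation 16).

A command-line interface mirrors the library:

```
ventnet build-network --seed 1 --d 0.2 --collapse 0.1 --out net.json
ventnet simulate --network net.json --out run/
ventnet ensemble --n 100 --out ens/
ventnet sweep --vt 4,8,12,16 --collapse 0.1,0.2,0.5,1.0 --d 0.2,0.5 --n 100 --out sweep/
```

Every run directory contains the fully resolved configuration and its
content hash, so results are reproducible from the emitted config and seed
alone.

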