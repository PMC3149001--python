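# mlcpath

Mass-action ODE model of **myosin light chain (MLC) activation in
endothelial cells** under thrombin, histamine and VEGF stimulation — the
signalling axis that drives endothelial hyper-permeability in thrombosis,
acute inflammation and tumour angiogenesis.

MLC phosphorylation is set by a kinase/phosphatase balance:

    MLC  ⇌  pMLC  ⇌  ppMLC        (kinases: Ca₄CaM–MLCK, phospho-MLCK, ROCK;
                                    phosphatase: MYCP)

with the reported observable the activated fraction of the conserved MLC
pool, `100·([pMLC]+[ppMLC])/MLC_total`. Upstream, the package wires the
three mediator cascades into one network: thrombin → PAR-1 → Gq
(PLCβ/IP3/Ca²⁺) and G12/13 (RhoGEF → Rho → ROCK); histamine → H1 → Gq and
eNOS→NO→sGC→cGMP→PKG; VEGF → VEGFR2 → PLCγ, eNOS, and Ras-Raf-MEK-ERK →
phospho-MLCK. MYCP is inhibited by ROCK-phosphorylated MYPT1 and by
PKC-phosphorylated CPI-17. ROCK must be opened by Rho-GTP before either
Rho or PKG can activate it — the structural AND-gate behind the
super-additive (synergistic) MLC activation seen when low doses of
thrombin are combined with histamine or VEGF.

The package provides, as importable modules and a CLI:

* `mlcpath.network` — generic mass-action / Michaelis–Menten reaction
  networks compiled to fast ODE right-hand sides (complex-arithmetic
  capable), stoichiometry, conserved-moiety detection, cascade switches;
* `mlcpath.pathway` — the curated endothelial model with stimulus
  configurations (doses, over-expression multipliers, cascade ablations);
* `mlcpath.simulate` — Dormand–Prince integration (abstol 1e-6, reltol
  1e-3, stiff fallback), activation series, peak detection, 10-min binned
  areas, combination-vs-additive synergy tables;
* `mlcpath.calibrate` — trust-region least-squares estimation of the free
  kinetic constants against printed validation features;
* `mlcpath.sensitivity` — local sensitivity via complex-step derivatives
  with a finite-difference fallback, and whole-table parameter ranking;
* `mlcpath.experiments` / `mlcpath.cli` — scripted reproduction of every
  in-silico experiment (validation suite, dose panels, ablations);
* `mlcpath.sbml` — SBML Level 3 export/import of the model.

## Worked example

Simulate thrombin stimulation (0.05 µM, histamine and VEGF absent) and
inspect the MLC activation curve:

```bash
mlcpath simulate --thrombin 0.05 --horizon 100 --out thrombin_run
```

```
MLC peak at 2.0 min: 71.0%
```

The printed peak is the fast Ca²⁺/CaM-MLCK transient; behind it the
slower Rho/ROCK phase holds activation near 66% through 30 min before the
receptor pool desensitizes (48% at 60 min) — the two-phase signature of
the thrombin response. `thrombin_run/` contains the observable time
courses (`observables.csv`) and a JSON run report (add `--plot` for a
PNG). The same experiment as a library call:

```python
from mlcpath import StimulusConfig, build_model, run, activation_series

net = build_model(StimulusConfig(thrombin=0.05))
tc = run(net, horizon=6000)                    # seconds, 1 s output grid
act = activation_series(tc, "mlc_activation_pct")
print(f"activation at 30 min: {act[1800]:.1f}%")   # -> 66.2%
print(f"activation at 60 min: {act[3600]:.1f}%")   # -> 48.4%
```

Synergy between low-dose thrombin and histamine (areas under the
activation-fraction curve per 10-min bin; `net_gain > 0` = synergistic):

```bash
mlcpath synergy --pair thrombin-histamine
```

Cascade ablations and over-expression panels:

```bash
mlcpath simulate --thrombin 0.05 --switch-off ca_dependent   # early peak gone
mlcpath panel --component VEGFR2 --levels 0.010,0.012 --vegf 0.02
mlcpath sensitivity --output ppMLC
mlcpath validate                                             # feature suite
```

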