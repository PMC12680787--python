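# transmural

Strategies that prolong the ventricular action potential without
increasing transmural dispersion of repolarization, studied in silico.

Class III antiarrhythmics that block I_Kr prolong the action-potential
duration (APD) but preferentially in mid-myocardial (MID) cells, which
*increases* the transmural dispersion of repolarization — the
arrhythmogenic substrate for Torsade de Pointes.  `transmural` packages
the computational machinery to look for multichannel interventions that
avoid this: a conductance-scalable O'Hara–Rudy (ORd) human ventricular
myocyte simulator (EPI / MID / ENDO variants), AP phase analytics,
dispersion and repolarization-reserve metrics, a ring-topology particle
swarm optimizer over seven channel-conductance multipliers, backward
feature elimination to rank the currents, and a population-of-models
sampler for dispersion maps.  It is aimed at computational
electrophysiologists studying multichannel ("amiodarone-like")
pharmacology.

## The quantities at the core

* **APD90** — from the end of depolarization (phase-0 spike) to 90 %
  repolarization of the AP amplitude APA = V_peak − V_rest.
* **Phases** — phase 1 ends when the total ionic current I_tot becomes
  (sustainably) positive, phase 2 when I_K1 reaches 10 % of its peak,
  phase 3 at APD90; APD = ph1 + ph2 + ph3.
* **Transmural dispersion** — max pairwise APD90 difference among the
  cell variants paced to steady state under the same scaling and basic
  cycle length (BCL); the single-cell proxy for tissue dispersion.
* **Repolarization reserve** — APD prolongation under a constant
  −0.1 pA/pF depolarizing current during the AP; bigger prolongation =
  less reserve.
* **Duration–current hyperbola** — the mean total current over phases
  2–3 obeys I ≈ K/d (K ≈ the potential change over repolarization),
  which is why equal current changes move long-APD cells further than
  short-APD cells — the mechanistic heart of the dispersion story.
* **Conductance scaling** — multipliers x on the maximum conductances of
  I_NaL, I_CaL, I_Ks, I_Kr, I_K1, I_NaK, I_NaCa within stated ranges;
  "blockers-only" caps them at 1.

## Worked example

```python
from transmural import Scaling, transmural_dispersion

control = transmural_dispersion(Scaling(), bcl=1000.0)
blocked = transmural_dispersion(Scaling(ikr=0.75), bcl=1000.0)
optimum = transmural_dispersion(
    Scaling(inal=0.0, ical=0.5, ikr=0.56, inak=0.95, inaca=0.5), bcl=1000.0)
for name, r in [("control", control), ("25% IKr block", blocked),
                ("multichannel optimum", optimum)]:
    print(f"{name:>22}: EPI {r.apd_epi:5.1f}  MID {r.apd_mid:5.1f} "
          f"dispersion {r.dispersion:5.1f} ms")
```

prints (converged pacing protocol):

```
               control: EPI 231.2  MID 332.7 dispersion 101.4 ms
         25% IKr block: EPI 271.3  MID 381.8 dispersion 110.4 ms
  multichannel optimum: EPI 268.0  MID 350.3 dispersion  82.3 ms
```

Selective I_Kr block prolongs the epicardial APD by ~40 ms but drives
dispersion *up* (101 → 110 ms) because MID prolongs more; the
multichannel blocker combination achieves the same epicardial
prolongation while pulling dispersion *down* (101 → 82 ms).

The same machinery is scriptable from the shell:

```bash
transmural simulate --cell epi --bcl 1000 -x ikr=0.75 --out beat.csv
transmural features --in beat.csv --out features.json
transmural dispersion -x iks=26.83 -x ikr=0 --bcl 1000 --out disp.json
transmural optimize --surrogate --seed 7 --out run.json
```

## Layout

| module | contents |
| --- | --- |
| `transmural.ord` | ORd cell model, scaling, pacing driver, threshold search |
| `transmural.ap_features` | phase segmentation, APD/APA, phase-mean currents, hyperbola fit |
| `transmural.dispersion` | dispersion metric, reserve protocol, EAD detection |
| `transmural.optimize` | PSO, objectives, ORd + surrogate evaluation backends |
| `transmural.elimination` | backward feature elimination |
| `transmural.popmodels` | population-of-models dispersion maps |
| `transmural.synthetic_ap` | analytic AP-shaped test waveforms |
| `transmural.io` / `transmural.cli` | config, serialization, provenance, CLI |

See `docs/methods.md` for the model assumptions, numerical choices and
their rationale.
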