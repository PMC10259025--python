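# vacef — noninvasive ejection fraction from ventricular–arterial coupling

Left-ventricular ejection fraction (EF) is the standard bedside index of
cardiac pump function, but measuring it requires echocardiography, which
cannot run continuously during surgery or in screening settings. `vacef`
implements an estimator that needs only quantities a cuff-and-ECG vascular
screening device already records: the pre-ejection period (PEP), the ejection
time (ET), and systolic/diastolic cuff pressures. It is aimed at
anesthesiologists, intensivists and hemodynamics researchers who want a
continuous, noninvasive EF surrogate, and at methodologists who want to study
the estimator's error structure on simulated cohorts.

## The model

End-systolic pressure is estimated from the cuff pressures by the Kappus
regression:

    Pes = 0.205·sBP + 0.898·dBP + 0.4214   [mmHg]

The ventricular–arterial coupling ratio x = Ees/Ea (end-systolic elastance
over effective arterial elastance) is obtained by combining the hypothetical
clamped-aorta peak pressure, Pmax = Pad·(1 + k·ET/PEP), with the coupling
identity Ees/Ea = (Pmax − Pes)/Pes and the empirical bilinear-elastance slope
ratio k = 0.53·x^0.51 (Pad is identified with cuff dBP). Eliminating Pmax
gives a single scalar equation,

    g(x) = (Pad/Pes)·(1 + 0.53·x^0.51·ET/PEP) − 1 − x = 0,

which `vacef` solves with a safeguarded Newton iteration (analytic derivative,
maintained sign-change bracket, bisection fallback). Because g is strictly
concave, up to two positive roots exist; the larger, physiologically stable
one is returned.

From x, ventricular efficiency and EF follow in closed form:

    Eff = 1/(1 + 0.5·Ea/Ees) = 1/(1 + 0.5/x)       (external work / PV area)
    EF  = Eff/(2 − Eff)                             (exact when V0 = 0)

where V0 is the ventricular volume at zero pressure. The package also ships
the pressure–volume-loop forward model (Ees, Ea, EW, PVA, Eff, EF from
volumes and Pes), which proves the EF shortcut algebraically at V0 = 0 and
quantifies its bias when V0 > 0; Bland–Altman agreement statistics with the
percentage-error ≤ 30% acceptability rule; and a synthetic-cohort simulator
whose subjects carry exact ground truth.

## Worked example

Solving the cohort-mean inputs of a 44-subject healthy-adult screening study
(PEP 97 ms, ET 303 ms, sBP 119 mmHg, dBP 72 mmHg):

```python
>>> from vacef import BeatRecord, beat_to_ef
>>> est = beat_to_ef(BeatRecord(pep=97, et=303, sbp=119, dbp=72))
>>> round(est.pes, 4), round(est.ees_over_ea, 4), round(100 * est.ef, 2)
(89.4724, 1.3676, 57.76)
```

Pes is 89.47 mmHg, the solved coupling ratio 1.37 sits well inside the
cohort's reported 1.5 ± 0.6, efficiency is 0.732, and the estimated EF of
57.8% matches the study's reported mean EF of 57 ± 9% — in the normal 50–70%
range, and below the echo EF (66 ± 5%) as observed in vivo.

The same computation from the shell, plus a synthetic cohort with automatic
agreement analysis against its simulated echo readings:

```text
$ vacef compute --input beats.csv --output results.csv
INFO rows=1 converged=1 warned=0 failed=0 -> results.csv

$ cat results.csv
id,pes_mmhg,ees_over_ea,k,pmax_mmhg,eff_percent,ef_eff_percent,converged,warnings
mean,89.4724,1.36763,0.621755,211.837,73.228,57.7636,True,

$ vacef simulate --n 44 --seed 1 --out-dir sim
INFO wrote 44 subjects to sim
$ vacef compute --input sim/beats.csv --output sim/results.csv
INFO rows=44 converged=44 warned=0 failed=0 -> sim/results.csv
INFO agreement vs echo: bias=0.07 sd=3.32 loa=(-6.58, 6.71) pe=11.8%
```

With the simulator's default 4-percentage-point echo noise and V0 = 0, the
pipeline is unbiased against the simulated echo (bias 0.07%) and the
percentage error (11.8%) is well inside the 30% acceptability bound —
the textbook behaviour the real study's larger in-vivo bias departs from.

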