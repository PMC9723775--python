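# isoprime

Quantitative analysis of ¹³C-phenolic-acid soil-priming experiments:
isotope mass-balance partitioning of respired CO₂, priming estimation
against water-only controls, DNA-SIP heavy-fraction enrichment calling of
degrader phylotypes, indicator-phylotype statistics, and qPCR-based
functional-gene (*pobA*) expression quantification — together with a
synthetic-data generator that emulates the microcosm, CsCl-gradient, and
qPCR designs so the whole pipeline runs with no external data.

## Who this is for

Soil microbial ecologists running stable-isotope-probing (SIP) priming
experiments: vials of soil amended with a ¹³C-labeled substrate (here
*p*-hydroxybenzoic acid, *p*HB, or glucose at 17.5 atom % ¹³C; 99 atom %
for field dosings), headspace CO₂ measured by GC/MS, degrader populations
resolved by CsCl buoyant-density gradients and 16S amplicon sequencing,
and degradation activity tracked by RT-qPCR of *p*-hydroxybenzoate
3-monooxygenase (*pobA*) transcripts.

## The model

Respired CO₂ is split into amendment-derived and native soil-organic-carbon
(SOC) pools with the two-member isotope mixing line

```
f_sub = (F_sample − F_nat) / (F_sub − F_nat)
C_sub = f_sub · C_total          C_soc = C_total − C_sub
```

where `F_sample` is the measured ¹³C atom fraction of respired CO₂,
`F_sub` the substrate atom fraction, and `F_nat` the natural-abundance
baseline estimated from unlabeled controls (≈ 0.0111). Primed SOC is the
SOC-derived respiration in excess of water-only controls:

```
primed(t) = mean C_soc,treatment(t) − mean C_total,control(t)
```

accumulated over flush-to-flush sampling intervals. DNA-SIP degrader
calls use the heavy-window fold-change rule: a phylotype is a degrader
when its mean normalized abundance in heavy gradient fractions (F3–F8,
≈ 1.74–1.76 g·mL⁻¹) is at least eightfold higher in ¹³C than in ¹²C
libraries (log₂ FC ≥ 3). Treatment-responsive phylotypes are scored with
the indicator value IndVal = A·B (specificity × fidelity) under a
permutation null, and *pobA* expression is quantified from Ct values via
a log-linear standard curve with detection-limit censoring
(~300 copies µL⁻¹).

## Worked example

```python
from isoprime.pipeline import PipelineConfig, run_pipeline

summary = run_pipeline(PipelineConfig(outdir="demo", seed=42))
```

which simulates a default microcosm experiment (water, ¹³C-*p*HB and
¹³C-glucose at 0.5 mg C g⁻¹; four replicate vials; seven daily headspace
samplings) plus a 20-fraction gradient experiment, and runs the full
estimation chain. Printing the key fields of `summary` gives:

```
pHB      primed C = +12.69 umol/g (truth +13.0), +8.62 % of control, recovery  97.1 %
glucose  primed C =  -1.46 umol/g (truth  -5.5), -0.99 % of control, recovery  66.4 %
Tukey letters: {'water': 'a', 'pHB': 'b', 'glucose': 'a'}
SIP: 12 phylotypes called 13C-enriched (12 truly labeled, 0 false)
indicator phylotypes at p<0.05: 95
pobA/16S ratios censored below detection: 16 of 24
```

The *p*HB arm shows strong positive priming (+12.7 µmol C g⁻¹ estimated
against an injected truth of +13, i.e. ~8.6 % extra SOC mineralization
relative to water controls) and near-complete substrate mineralization;
glucose shows weak negative priming and ~66 % recovery. The SIP caller
recovers all 12 labeled degrader phylotypes with no false positives, and
*pobA* transcripts fall below the detection limit once the substrate is
exhausted. The same stages are available as CLI subcommands
(`isoprime simulate | flux | priming | sip | indval | qpcr | run`).

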