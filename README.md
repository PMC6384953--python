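# gammaopto

Analysis pipeline for optogenetic electrophysiology sessions: detection of
transient gamma-band oscillations in the LFP, classification of single units
by their photostimulation response, spike–gamma coupling statistics, laser
ON/OFF spectral comparisons, and behavioral scoring (open-field locomotion,
Y-maze spontaneous alternation). A synthetic-session generator with ground
truth makes every stage testable without any recordings.

## Modules

| module | contents |
| --- | --- |
| `gammaopto.session` | data model (`LFPSignal`, `SpikeTrain`, `LaserProtocol`, `BehaviorTrack`, `ArmEntrySequence`, `RecordingSession`), TSV/binary session directory I/O, epoch algebra (`epoch_complement`) |
| `gammaopto.synth` | `SimConfig`-driven generators: pink-noise LFP with embedded gamma bursts, laser-suppressed/excited/unaffected units with optional von-Mises gamma phase locking, laser protocols, open-field tracks, Y-maze entries — all deterministic per seed, with `GroundTruth` |
| `gammaopto.gamma` | envelope-threshold gamma-event detector (downsample → zero-phase FIR band-pass 20–80 Hz → rectify → 4th-order Butterworth 20 Hz low-pass → z-score → 2 SD threshold, 1 SD boundaries, 150 ms refractory merge and minimum duration), 7-cycle complex-Morlet event characterization, event-density ON/OFF comparison |
| `gammaopto.units` | peri-event time histograms, sliding-sweeps permutation test (±15 s window, 500 ms bins, basal-rate-normalized template vs 100 interval-shuffled surrogates), paired ON/OFF unit classification, photoinhibition latency, population summaries |
| `gammaopto.coupling` | pairwise phase consistency (closed form), PPC spectra from analytic-signal phases, event-triggered spike correlograms with 500 circular-shift surrogates, per-event firing-rate vs gamma-magnitude correlation, single-unit vs multi-unit multitaper coherence (TW=3, 5 tapers) |
| `gammaopto.spectral` | multitaper PSD (DPSS tapers, K = 2TW−1, W = TW/epoch), 1/f normalization, ON/OFF PSD ratio with per-frequency Wilcoxon + Benjamini–Hochberg FDR and 50 Hz notch excision, gamma-band power with normality-gated paired test |
| `gammaopto.behavior` | tracked speed with rest/run stratification, laser-triggered speed averages, spontaneous-alternation index (with 30 s block time course), normality-gated group comparisons (t/ANOVA+Tukey vs Mann-Whitney/Kruskal) |
| `gammaopto.stats` | shared utilities: KS normality gate, paired comparison, BH-FDR |

## CLI

```sh
gammaopto simulate --out sess/ --seed 1 --kind vp --ymaze
gammaopto detect-gamma --session sess/ --out events.tsv
gammaopto classify-units --session sess/ --out classes.tsv
gammaopto coupling --session sess/ --events events.tsv --out-prefix out/
gammaopto spectral --session sess/ --out-prefix out/
gammaopto behavior --session sess/ --out-prefix out/
```

A session directory holds `lfp.bin` (little-endian float64) + `lfp.json`
sidecar, `spikes.tsv`, `laser.tsv`, optional `track.tsv`/`ymaze.tsv`, and
`meta.json`; all times are seconds from session start, intervals half-open.

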