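# voltplace

Analysis pipeline for **1 kHz voltage imaging of hippocampal CA1 neurons
during virtual-track navigation**: from fluorescence movies or traces plus
behavior logs to spikes, subthreshold membrane-potential dynamics,
place-cell statistics, behavioral-timescale plasticity (BTSP) metrics,
excitability (F-I) curves, and optogenetically evoked synaptic-response
classification. A first-class synthetic-session generator produces every
input with recorded ground truth, so each stage of the pipeline can be
validated against known targets.

It is written for experimenters and analysts working with genetically
encoded voltage indicator (GEVI) recordings — or with any kHz-rate optical
membrane-potential proxy — who need a tested, scriptable reimplementation of
the standard analysis chain for place fields and plasticity protocols.

## The analysis in brief

**Spikes.** Optical action potentials are detected by threshold-and-maximum
on a high-passed trace: noise σ is estimated as 1.4826 × MAD, crossings at
4σ (per-cell adjustable) mark spikes, and spike height — the median peak
amplitude above local baseline — defines the cell's amplitude unit
(SNR = spike height / σ). For Gaussian noise the analytic error model gives
the expected false positives per record as (1 − p₄)/2 · f_s · T with
p₄ = erf(4/√2) = 0.999937, and the per-spike miss probability as the
Gaussian tail beyond (SNR − 4)σ; at SNR 8.8 that is Φ̄(4.8) ≈ 7.93 × 10⁻⁷.

**Subthreshold signals.** Spikes are deleted (linear interpolation over
−3/+6 ms) and the residual is normalized to spike height
(ΔV_m = (low-passed F − record mean)/spike height). The <3 Hz component is
the subthreshold ramp, the 6–10 Hz Hilbert envelope is the theta amplitude
(both zero-phase 201-tap Hamming FIR designs), and plateau-driven complex
spikes are >10 ms excursions above 0.4 spike height of the 20 ms-smoothed
trace that carry a burst of riding spikes.

**Spatial maps and place cells.** The 180 cm track is divided into 80 bins
(2.25 cm); samples slower than 5 cm/s are discarded; rate = spikes/occupancy,
smoothed with a 5-point Gaussian (σ = 1 bin). Spatial tuning is quantified as

    SI = Σᵢ pᵢ (λᵢ/λ) log₂(λᵢ/λ)   [bits/spike]

and tested against a null built by circularly permuting each trial's
firing-rate series relative to position (1000 shuffles; place cell ⇔
observed SI > 95th percentile). Place fields are contiguous runs above
0.25 × peak rate, longer than 4 bins, with in-field mean > 1.5 Hz and
> 2.5 × the out-of-field mean.

**Protocols.** Closed-loop induction sessions are split into Pre/Stim/Post
epochs around a 300 ms stimulus at a fixed track location; plasticity is
read out as the anticipatory firing rate 10–30 cm before that location and
the backward shift of the induced field peak. Excitability is the slope of
firing rate vs. stimulus intensity over 500 ms steps. Synaptic responses to
20 ms presynaptic test pulses are classified excitatory/inhibitory from the
evoked-spike count (window ≤ 26 ms) and the signed area (AUC) of the
baseline-subtracted, spike-removed stimulus-locked response.

## Worked example

Run the bundled closed-loop plasticity protocol end to end on synthetic
data (Pre 10 / Stim 6 / Post 20 trials, stimulus at 90 cm, induced field
shifted −12 cm):

```python
import voltplace as vp

report = vp.run_pipeline({
    "seed": 1,
    "mode": "plasticity",
    "simulate": {"n_pre": 10, "n_stim": 6, "n_post": 20},
    "placecells": {"n_shuffles": 1000},
})
cell = report["cells"]["cell0"]
print(cell["n_spikes"], round(cell["snr"], 2))
print(cell["plasticity"]["anticipatory_rate_hz"])
print(cell["plasticity"]["backward_shift_cm"])
print(cell["place_cell"])
```

prints

```
1010 9.06
{'Pre': 2.12, 'Stim': 0.99, 'Post': 6.95}
-10.125
{'si_bits_per_spike': 0.3773, 'percentile': 100.0, 'is_place_cell': True, 'n_fields': 1}
```

Reading: 1010 spikes were detected at SNR 9.06 (the generator's target is
8.8). Anticipatory firing 10–30 cm before the stimulated location rose from
2.1 Hz (Pre) to 7.0 Hz (Post), the induced field peak sits 10.1 cm before
the stimulation site (one 2.25 cm bin from the injected −12 cm shift), and
the Post-epoch map passes the 1000-shuffle place-cell test with one
identified field. (The report's complex-spike table for such sessions also
contains the 300 ms stimulus-evoked plateaus, which is why their mean
duration exceeds the ~46 ms of spontaneous events.)

The same stages are scriptable from the shell:

```bash
voltplace simulate --mode trace --seed 4 --out sim/
voltplace spikes --traces sim/traces.csv --out spk/
voltplace placecells --traces sim/traces.csv --behavior sim/behavior.csv \
    --shuffles 1000 --seed 1 --out pc/
voltplace run --config demo.yaml --out results/
```

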