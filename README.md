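# finwave

Analysis toolbox for zebrafish undulatory-swimming studies: a
standing/travelling wave model of body bending with an elongated-body
propulsion layer, plus the full measurement pipeline that such a study
needs — synthetic video and trace generation with ground truth, midline
tracking, kinematic and positional features, Mauthner-cell
field-potential analysis, axon morphometry with operator blinding,
frameshift-allele sequence arithmetic, and permutation statistics.

## The scientific problem

Zebrafish swim by superimposing two bending waves on their body: a
**standing wave** over the pectoral region, whose spatial envelope
oscillates in place, and a **travelling wave** that propagates
rostro-caudally and generates thrust. In motor-neuron degeneration
models the longest (most caudal) motor neurons fail first, effectively
stiffening the tail and damping the travelling wave. The central
question this package's model addresses: *can the fish compensate by
enlarging its pectoral standing wave, and if so, where must that wave's
peak sit?*

The bending field is parameterised as

```
theta(s, t) = A_st · G(s; p, w) · cos(2π f t)
            + γ(s) · A_tr · s^q · cos(2π f t − 2π s / λ)
```

with `s` the arc-length fraction (0 = snout, 1 = tail tip), `G` a
Gaussian envelope with peak position `p` and width `w`, and `γ(s)` a
stiffness factor that drops from 1 to `stiffness_gamma` caudal to
`stiffness_onset`. Midlines are reconstructed by integrating unit
tangents (inextensible body), tail-tip kinematics `h, ḣ, h′` are
measured about the per-frame mean swimming axis, and the steady speed
`U` solves the elongated-body thrust–drag balance

```
(m_a/2) · (⟨ḣ²⟩ − U²⟨h′²⟩)  =  ½ ρ C_d A_w U²,   m_a = ρ π (b/2)²
```

where `b` is the tail-tip span. Observed bending fields can be
decomposed back into standing and travelling parts via the spatial
analytic signal, yielding a per-segment travelling index and the
pectoral bending-peak position.

## Worked example

```bash
python examples/01_wave_model_compensation.py
```

prints, with the shipped presets:

```
Steady swimming speed per condition (body lengths per second):
  flexible      1.191 BL/s
  stiff         0.320 BL/s
  compensated   1.244 BL/s

Grid search over standing-wave (amplitude, peak position):
  fastest pair: amp=0.090 rad, peak=0.45 BL
  pairs within 5% of the flexible speed: 4
```

Stiffening the caudal half (γ = 0.3) cuts the model fish's cruising
speed to about a quarter. Enlarging the standing wave 1.8× **and**
shifting its peak caudally from 0.25 to 0.35 body lengths restores the
speed to within ~5% of the fully flexible condition; the grid search
confirms that the fastest compensating configurations all place the
standing-wave peak caudal to the wildtype position. The other examples
(`examples/02`–`06`) walk through video tracking, arena occupancy,
escape/field-potential analysis, blinded morphometry and allele
arithmetic the same way, each printing the numbers it computes and what
they mean.

A thin CLI exposes the same pipeline stages from the shell
(`finwave simulate|track|features|ephys|axons|model|stats|reproduce-fig2f`);
every run writes a manifest (seed, config hash, versions, file hashes)
so outputs are reproducible.

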