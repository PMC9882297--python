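# locusdyn

Analysis toolkit for the joint stochastic motion and transcriptional output
of pairs of distal DNA loci — an enhancer region and a reporter promoter —
tracked live across a panel of genomic separations. It is aimed at
quantitative biologists and biophysicists who have (or want to simulate)
two-locus trajectory tables: per-frame 3-D positions of both loci,
a nascent-transcription intensity channel, and a genomic separation *s*
per cell.

The package covers the full analysis chain:

* **Synthetic data with ground truth** — Brownian-dynamics simulation of an
  ideal bead-spring (Rouse) chain, and a tunable stationary
  Gaussian-process surrogate for the anomalous regime observed in embryos,
  plus three-state pairing/transcription kinetics and a measurement model
  (localization noise, dropouts, intensity).
* **Topological-state inference** — a three-state hidden Markov model
  (O_off open, P_off paired-silent, P_on paired-transcribing) on joint
  distance + intensity series, with Maxwell-type radial distance emissions,
  masked-frame marginalization, and forbidden direct O_off ↔ P_on
  transitions.
* **Pairing kinetics** — censoring-aware dwell-time extraction,
  Kaplan–Meier survival curves, exponential-MLE lifetimes, frame-weighted
  pairing probabilities P(s), and weighted log-log power-law fits.
* **Polymer dynamics** — single- and two-locus MSDs with
  bootstrap-over-nuclei errors, Bayesian fits of the ideal-chain two-locus
  MSD closed form, diffusivity and relaxation-time scaling, autocorrelation
  data collapse, and parameter-free velocity cross-correlation predictions.

## The model in brief

A locus on a polymer subdiffuses, M1(t) = Γt^β, with β = 2/(2+d) set by the
fiber's fractal dimension d. The separation vector of a locus pair has
two-locus MSD M2(t) crossing over from 2Γt^β to the plateau 2⟨R²⟩ at the
relaxation time τ = (⟨R²⟩/Γ)^{1/β}; for the ideal chain (β = 1/2),

    M2(t) = 2Γ√t (1 − e^{−τ/(πt)}) + 2J erfc(√(τ/(πt))),  τ = (J/Γ)².

With ⟨R²⟩ ~ s^{2/d} and Γ(s) ~ s^α, relaxation times scale as τ ~ s^γ with
γ = (2/d − α)/β: an ideal chain gives γ = 2, a crumpled globule 5/3, while
the measured combination (1/d ≈ 0.31, α ≈ 0.27, β ≈ 0.52) gives the
anomalously shallow γ ≈ 0.7 — locus encounter times almost independent of
genomic distance. The normalized velocity cross-correlation intercept
Cvv(0)/Cv(0) = 1 − M2(δ)/(2M1(δ)) depends only on δ/τ and provides a
parameter-free consistency check. See `docs/methods.md` for the full
treatment.

## Worked example

Recovering the anomalous relaxation-time scaling from synthetic data
(`examples/02_surrogate_relaxation_scaling.py`):

```bash
$ python examples/02_surrogate_relaxation_scaling.py
s =    58 kb: tau =     93 s (generator truth    107 s)
s =   149 kb: tau =    180 s (generator truth    201 s)
s =   190 kb: tau =    228 s (generator truth    237 s)
s =   330 kb: tau =    352 s (generator truth    344 s)
s =   595 kb: tau =    495 s (generator truth    511 s)

tau(s) ~ s^gamma: gamma = 0.739 +/- 0.044
autocorrelation collapse:   gamma = 0.680 +/- 0.118
generator ground truth:     gamma = 0.673
```

Each line fits one separation's two-locus MSD to extract its relaxation
time; the regression of log τ on log s and the independent autocorrelation
data collapse agree on γ ≈ 0.7, the generator's plug-in value
(2·0.31 − 0.27)/0.52 — compare with γ = 2 for an ideal chain
(`examples/01_rouse_chain_msd.py` and target `t12` below). The other
examples cover state inference (`03`), burst lifetimes (`04`), the
end-to-end pipeline (`05`), and velocity cross-correlations (`06`).

The pipeline also has a thin CLI:

```bash
locusdyn all --config config.yaml --outdir run/
```

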