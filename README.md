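# h3k27sim

Stochastic kinetic simulation of the H3K27 modification landscape around
transcription start sites, with the parameter-inference scheme that fits the
model to perturbation ChIP profiles.

## The problem

Polycomb-target genes in mouse embryonic stem cells carry broad
H3K27me3 domains around their promoters; active genes instead show
H3K27ac and H3K27me1.  These landscapes emerge from a competition between
histone-modifying enzymes: PRC2 (recruited at CpG islands, read out here
through its SUZ12 subunit) methylates K27 stepwise and — when bound to an
H3K27me3 nucleosome — is allosterically activated and can methylate distal
sites it contacts in 3D; UTX demethylates; p300 acetylates; HDACs
deacetylate; histone turnover and DNA replication continually inject
unmodified histones.  `h3k27sim` implements this reaction network on a
lattice of 200 H3 tails (20 kbp) and asks whether enzyme occupancy profiles
alone quantitatively explain the observed mark profiles, their dynamics,
and their response to perturbations.

Per-site propensities (h⁻¹), with ψ the enzyme occupancy densities:

    me_{x-1} -> me_x :  k_mex ψ_SUZ12(i) + ε_mex Σ_j |i-j|^-λ ψ_SUZ12(j) 1[j=me3]
    me_x -> me_{x-1} :  γ_me ψ_UTX(i)
    u -> ac          :  k_ac ψ_p300(i)
    ac -> u          :  γ_ac
    X -> u           :  γ_turn          (turnover, any modified X)

plus replication every T hours, resetting each site to u with probability ½.
The spreading-to-nucleation ratio R = ε_mex/k_mex is shared by all
methylation steps.  Wild-type defaults: k_me3 = 0.81 h⁻¹,
k_me1 = k_me2 = 3·k_me3, R = 0.85, γ_me = 1.5 h⁻¹, k_ac = 1.03 h⁻¹,
γ_ac = 0.6 h⁻¹, γ_turn = 0.03 h⁻¹, T = 13.5 h, λ = 1.

## Worked example

```python
from h3k27sim import ModelParams, crossover_distance, make_preset_profile
from h3k27sim.observables import steady_state_ensemble, window_valency

profile = make_preset_profile("pcg_target")     # PcG-target-like enzyme peaks
ensemble = steady_state_ensemble(profile, ModelParams(), n_traj=24,
                                 burn_in_cycles=15, sample_cycles=4, seed=1)
profiles = ensemble.steady_profiles()
window = profile.lattice.window_indices(2.5)
for name in ("u", "ac", "me1", "me2", "me3"):
    print(name, round(profiles[name][window].mean(), 3))
print(window_valency(profiles, profile.lattice).label)
print(crossover_distance(profiles["me3"], profiles["me2"], profile.lattice))
```

prints (seed 1):

```
u 0.031
ac 0.014
me1 0.04
me2 0.201
me3 0.715
pcg_like
5.8
```

me3 dominates the ±2.5 kbp promoter window (71.5%, more than 1.5× the me2
level — a PcG-like valency) and is overtaken by me2 about 5–6 kbp from the
TSS, where allosteric spreading no longer outruns demethylation and
replication dilution.

The `examples/` directory has one short script per capability: steady-state
profiles, the recruitment phase diagram, cell-cycle/pool dynamics and the
effective histone decay time, inhibitor washout, and parameter inference.
A thin CLI wraps the same functions:

```bash
h3k27sim simulate --preset pcg_target --seed 1 --out out/
h3k27sim dynamics --protocol washout --out out/
h3k27sim phase-diagram --alphas 0:1.4:0.2 --betas 0:2:0.2 --out out/
```

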