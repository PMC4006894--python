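# Simulation configuration accepted by `thermogrowth simulate --config`.
# Every field is optional: omitted group means fall back to the built-in
# reference values for that thermal group, and omitting `groups` entirely
# uses the default five-group compilation (2/6/2/2/2 strains).
points_per_strain: 14
noise_sd: 0.02          # SD of the observation noise on the sqrt(rate) scale
universal:              # universal protein-unfolding parameters
  dH_star: 4874.0       # J per mol amino-acid residue
  dS_star: 17.0         # J/(K mol-residue)
  T_H: 375.5            # K
  T_S: 390.9            # K
groups:
  - name: psychrophile
    n_strains: 2
  - name: mesophile
    n_strains: 6
    dH_act_mean: 75300.0    # J/mol
    dCp_mean: 59.9          # J/(K mol-residue)
    n_mean: 422.0           # residues
    dH_act_sd: 2000.0       # between-strain SDs
    dCp_sd: 1.0
    n_sd: 15.0
  - name: ascomycota
    n_strains: 2
  - name: thermophile
    n_strains: 2
  - name: hyperthermophile
    n_strains: 2
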