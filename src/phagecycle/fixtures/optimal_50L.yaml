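# Optimized 50 L two-stage self-cycling phage production scenario.
#
# Operational values are the optimum found by the two-round semi-exhaustive
# grid search over sensor levels, cycle time and influent substrate
# concentrations; kinetics are the E. coli reference parameterization with
# growth-rate-dependent infection curves.

kinetics:
  mu_max: 0.7726      # 1/h
  Km: 0.0727          # ug/mL
  e: 1.0e-6           # ug substrate per cell
  dX: 0.0             # 1/h, endogenous bacterial decay
  dP: 0.0             # 1/h, phage decay
  M: 10               # infection-parameter bins
  N: 50               # age classes per bin
  response:
    ki_at_zero: 1.0e-9    # mL/h
    ki_at_max: 1.0e-7     # mL/h
    latent_at_zero: 0.8   # h
    latent_at_max: 0.4    # h
    burst_at_max: 90.0    # phages/cell

process:
  scf:
    hls: 50.0                 # L
    lls: 11.6                 # L
    influent_substrate: 1000.0  # ug/mL
  sci:
    hls: 50.0                 # L
    mls: 40.0                 # L
    lls: 1.0                  # L
    influent_substrate: 316.0   # ug/mL
  cycle_time: 2.75            # h
  n_cycles: 45
  initial_inoculum: 1.0e6     # cells/mL in the growth vessel at start-up
  initial_phage: 1.0e8        # particles/mL in the infection vessel at start-up

costs:
  operation_rate: 40.0   # $/h, personnel + utilities + maintenance
  substrate_cost: 0.1    # $/g
  medium_cost: 15.0      # $/L prepared sterile medium

experiments:
  search:
    rounds: 2
    parameters:
      - {name: LLS_SCF, lower: 10.0, upper: 40.0, scale: linear, levels: 4}
      - {name: MLS_SCI, lower: 10.0, upper: 40.0, scale: linear, levels: 4}
      - {name: cycle_time, lower: 0.5, upper: 5.0, scale: linear, levels: 4}
      - {name: S_in_SCF, lower: 1.0, upper: 1000.0, scale: log, levels: 4}
      - {name: S_in_SCI, lower: 1.0, upper: 1000.0, scale: log, levels: 4}
  sensitivity:
    delta: 0.01
  interactions:
    deltas: [-0.02, -0.01, 0.0, 0.01, 0.02]
  dose_study:
    cell_conc: 1.0e6     # cells/mL target population
    ki: 1.0e-7           # mL/h
    latent: 0.5          # h
    burst: 67.5          # phages/cell
    duration: 1.0        # h
    target_fraction: 0.9

output_dir: runs
seed: 0
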