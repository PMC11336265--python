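# Baseline constants for the three heavy-metal biosensors.
# Every tunable the package uses lives here; modules read it once at import.

[kinetics]
n_copies = 15        # circuit copies per cell
alpha_R = 2.0        # repressor synthesis, molecules/min per copy
delta_R = 0.05       # repressor decay, 1/min
delta_D = 0.05       # metal-repressor dimer decay, 1/min
delta_C = 0.05       # chromoprotein decay, 1/min
k_unbind = 0.1       # dimer dissociation, 1/min
K_rep = 50.0         # repression half-constant, molecules
hill = 2.0           # Hill coefficient of repression
alpha_C = 1.0        # chromoprotein synthesis, molecules/min per copy
on_fraction = 0.5    # promoter activity above which a copy counts as ON
k_bind = 0.01        # metal-repressor association, (ug/L)^-1 min^-1;
                     # recalibrated per sensor so the activation threshold holds

[thresholds]         # activation thresholds, ug/L
arsenic = 10.0
mercury = 6.0
lead = 10.0

[concentrations]     # tested environmental concentrations, ug/L
arsenic = [10.0, 5.0, 0.0]
mercury = [6.0, 3.0, 0.0]
lead = [10.0, 5.0, 0.0]

[population]
error_rate = 0.001            # induced circuit-malfunction probability per step
growing_initial = 1000
growing_max = 20000
stationary_initial = 1999
stationary_max = 2000
growth_rate_growing = 0.023       # 1/min, ~30 min doubling
growth_rate_stationary = 1e-6     # 1/min, virtually no reproduction
maturation_delay = 20.0           # min before an ON cell shows visible reporter
t_end_growing = 190.0             # min
t_end_stationary = 240.0          # min
dt = 1.0                          # colony step, min
colony_radius_growing = 150.0     # um, initial seeding disk

[field]
domain_size = 800.0   # um, square side
dx = 10.0             # um, grid spacing
D_coeff = 30000.0     # um^2/min, small-molecule diffusion
source_radius = 100.0 # um, central pour zone

[part_lengths]        # placeholder fixture lengths, bp
constitutive_promoter = 35
repressible_promoter = 35
rbs = 15
cds = 700
terminator = 80
double_terminator = 129
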