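"""Calibrate the migration time-dilation parameter alpha.

The aggregation PDE runs on a faster clock than the ensemble-averaged
ABM; multiplying the transport term by alpha < 1 dilates time to match.
Here the "data" are generated by the PDE itself with a known alpha, so
the printed fit demonstrates parameter recovery: the estimate lands
within a percent of the generating value, and the trace shows the
roughly convex objective the search exploits.
"""

import numpy as np

import abmlink as al
from abmlink.grids import GridSpec

potential, _, _, domain = al.melanophore_preset(2)
grid = GridSpec.regular(domain, 48)
region = al.make_region("box", domain)
initial = al.uniform_initial_density(region, 400.0, grid)
schedule = al.SimulationSchedule(dt_pde=0.05, t_final=20.0)

truth = 0.7
sol = al.solve_continuum("movement", initial, al.ContinuumParams(alpha=truth),
                         potential, schedule)
ea = al.EnsembleDensity(fields=sol.fields, n_sim=1, count_mean=sol.mass,
                        count_std=np.zeros_like(sol.mass))

fit = al.fit_alpha(ea, initial, potential, schedule)
print(f"generating alpha = {truth}; fitted alpha = {fit.estimates['alpha']:.4f} "
      f"({abs(fit.estimates['alpha']/truth-1)*100:.2f}% off)")
print(f"objective at the optimum: {fit.objective:.3e}")
coarse = [(p['alpha'], v) for p, v in fit.trace[:13]]
print("coarse scan (alpha -> squared L2 error):")
for a, v in coarse[::3]:
    print(f"  {a:5.2f} -> {v:.3e}")
print("the single alpha=1 solve was resampled in time for every candidate "
      "(time-dilation fast path)")
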