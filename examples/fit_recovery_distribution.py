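"""Estimate per-subject metabolic recovery days and fit their GEV law.

Draws recovery times from the study-scale generalized extreme value
distribution (location 62.44 d, scale 30.16 d, shape 0.34), refits them by
maximum likelihood, and reports the quantities a reader of the recovery
analysis cares about: the fitted parameters, the most probable recovery
day (the density mode), and the model and empirical 95% quantiles.
"""
import numpy as np
from scipy import stats as sps

from phenorevert.recovery import fit_gev

true = {"location": 62.44, "scale": 30.16, "shape": 0.34}
rng = np.random.default_rng(0)
days = sps.genextreme.rvs(-true["shape"], loc=true["location"],
                          scale=true["scale"], size=351, random_state=rng)

fit = fit_gev(days)
print(f"n = {fit.n}, converged = {fit.converged}")
print(f"location {fit.location:6.2f} d   (generating value {true['location']})")
print(f"scale    {fit.scale:6.2f} d   (generating value {true['scale']})")
print(f"shape    {fit.shape:6.3f}     (generating value {true['shape']})")
print(f"most probable recovery day (mode): {fit.mode():.1f} d")
print(f"model 95% quantile: {fit.quantile(0.95):.0f} d; "
      f"empirical 95% quantile: {np.quantile(days, 0.95):.0f} d")
# The positive shape produces the long right tail: a minority of subjects
# takes several times the modal ~60 days to renormalize their metabolome.
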