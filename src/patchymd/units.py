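"""Reduced-unit conventions used throughout the package.

Every quantity is expressed in reduced units built from the particle
diameter sigma (length), the full patch-patch well depth epsilon (energy)
and the particle mass m:

* temperature      T* = kB T / epsilon
* number density   rho* = N sigma^3 / V
* time             t* = t sqrt(epsilon / (m sigma^2))
* surface tension  gamma in epsilon/sigma^2, or kB T/sigma^2 when divided
  by the run temperature T*.

The particle mass is unity and the rotational inertia is that of a uniform
sphere of diameter sigma, I = (2/5) m (sigma/2)^2 = 0.1 m sigma^2.  Any
consistent alternative choice rescales all kinetic observables uniformly.
"""

MASS: float = 1.0
INERTIA: float = 0.1  # uniform sphere, diameter sigma, unit mass
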