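"""Fingerprint stability under clone turnover.

Clone frequencies follow Brownian motion in log-space with drift -1/tau and
diffusion 1/theta; with theta = tau/2 this reproduces the empirical
clone-size power law rho(f) ~ f^-2. The expected sharing between a sample
taken today and one taken t years from now decays as clones drift to
extinction. tau is the clone turnover time: small tau erodes the fingerprint
within a few years, large tau preserves it for decades.
"""

import numpy as np

from immfp import DynamicsParams, SyntheticConfig, fingerprint_decay, generate_repertoire

rep = generate_repertoire(SyntheticConfig(seed=3))
M = 5000
times = [0.0, 0.5, 1.0, 2.0, 5.0, 10.0]

print(f"{'tau (y)':>8} | " + " ".join(f"t={t:<4g}" for t in times) + "   (<S>(t)/<S>(0))")
for tau in (0.66, 2.0, 10.0):
    params = DynamicsParams(tau=tau, seed=0)  # theta defaults to tau/2
    decay = fingerprint_decay(rep, M, params, times)
    S0 = decay[0][1]
    rel = [S / S0 for _, S, _ in decay]
    print(f"{tau:>8} | " + " ".join(f"{x:6.3f}" for x in rel))

print(
    "\nEach row is one turnover rate; columns show the expected shared-clonotype"
    "\ncount relative to a same-day replicate. With tau of a few years the"
    "\nfingerprint loses only a modest fraction of its sharing over a decade."
)
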