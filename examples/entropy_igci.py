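"""Entropy estimation and information-geometric cause-effect scoring.

Checks the kDP entropy estimator against closed forms, then scores a
deterministic mechanism Y = X^2: the mechanism leaves the cause with
the larger entropy, so the score H(Y) - H(X) is negative.
"""

import numpy as np

from rccm import igci_score, kdp_entropy

rng = np.random.default_rng(0)
n = 10_000

h_u = kdp_entropy(rng.uniform(0, 1, n))
h_g = kdp_entropy(rng.normal(0, 1, n))
print(f"H(U(0,1))  = {h_u:+.4f} nats   (closed form 0)")
print(f"H(N(0,1))  = {h_g:+.4f} nats   (closed form {0.5*np.log(2*np.pi*np.e):.4f})")

x = rng.uniform(0, 1, n)
res = igci_score(x, x**2)
print(
    f"Y = X^2:  score = {res.score:+.4f}  (closed form {np.log(2)-1:+.4f}), "
    f"inferred direction: {' -> '.join(res.inferred_direction)}"
)
print()
print(
    "The score is the entropy difference after rescaling both samples\n"
    "to [0,1]; below -0.2 it decides X -> Y.  This is the arbiter used\n"
    "to mask cross-map links under strong instantaneous coupling."
)
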