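"""How the relevance of a world disturbance is inferred from one movement.

Compares the two likelihoods over the observed rotation angle theta_y — one
assuming some world rotation is acting, one assuming none — and shows the
Bayesian posterior they produce.
"""

import math

from reachsim import RelevanceState, likelihood_irrelevant, likelihood_relevant, update_relevance
from reachsim.relevance import ObservedRotation

sigma = math.radians(2.5)  # angular observation noise scale

print("theta_y    L(relevant)  L(irrelevant)  posterior from P=0.5")
state0 = RelevanceState(p_relevant=0.5, sigma_theta=sigma)
for deg in (0.0, 2.5, 5.0, 10.0, 30.0):
    ty = math.radians(deg)
    l1 = likelihood_relevant(ty, sigma)
    l0 = likelihood_irrelevant(ty, sigma)
    post = update_relevance(state0, ObservedRotation(ty, 0.0)).p_relevant
    print(f"{deg:6.1f}    {l1:10.4f}  {l0:12.4f}  {post:20.6f}")

print("\nSmall observed rotations argue for 'no world disturbance'; beyond the")
print("likelihood crossing (~10 deg) any rotation is overwhelming evidence that")
print("a world disturbance is in play, so the world estimate becomes adaptable.")
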