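"""Evolve one random 7-actor network to a corner and classify it.

Draws all 42 directed relations uniform on (-1, 1), integrates
d x_ij/dt = (1 - x_ij^2) sum_k x_ik x_kj until every relation is within
1e-8 of +-1, reduces the corner to its class graph and prints the
archetype, the class sizes and each actor's self-evaluation F.
"""

import numpy as np

import signedbalance as sb

rng = np.random.default_rng(7)
x0 = sb.random_initial(7, rng)
result = sb.evolve(x0)
print(f"converged: {result.converged} at t = {result.t_end:.2f}")

sign = result.sign
partition = sb.refine_classes(sign)
graph = sb.class_graph(sign, partition)
template = sb.identify_template(graph)
f = sb.self_evaluation(sign)

print(f"class sizes: {graph.sizes}")
print(f"archetype:   {template.kind} {template.sizes}" if template
      else "archetype:   other")
print(f"F per actor: {[int(v) for v in f]}")
print(f"actors with F < 0: {[i + 1 for i, v in enumerate(f) if v < 0]}")
# A typical outcome is the three-class CIII structure: two hostile
# groups plus a small rejected class whose F is negative.
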