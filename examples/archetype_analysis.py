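"""Closed-form analysis of the archetype fixed-point configurations.

Builds the four generic class-graph archetypes (HB, CII, CIII, CIV) as
explicit sign matrices, checks their stationarity under the sign
condition s_ij = sign(sum_k s_ik s_kj), and prints the per-class
self-evaluation index F.  Negative F marks actors whose liking of
others is mostly unreciprocated.
"""

import signedbalance as sb

specs = [
    sb.TemplateSpec("HB", (4, 3)),
    sb.TemplateSpec("CII", (5, 2)),
    sb.TemplateSpec("CII", (4, 3)),
    sb.TemplateSpec("CIII", (3, 3, 1)),
    sb.TemplateSpec("CIV", (4, 3, 2, 1)),
]

for spec in specs:
    s = sb.make_template(spec)
    report = sb.is_stationary(s)
    f = sb.template_self_evaluations(spec)
    print(f"{spec.kind}{spec.sizes}: stationary={report.stationary} "
          f"(closed form: {sb.template_stable(spec)}), per-class F={f}")

# CII (5, 2) is a fixed point because N1 > N2 + 2, while CII (4, 3) is
# not (internal class-1 links lose the third-party vote).  In CIII and
# CIV the classes with F < 0 are the small "rejected aspirant" classes.
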