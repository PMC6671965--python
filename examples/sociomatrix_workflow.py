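"""Sociometric workflow: valued X/Y matrices to a classified class graph.

Writes a small synthetic pair of valued nomination matrices in UCINET DL
full-matrix form (positive nominations X, negative nominations Y),
combines them as (X - Y)/5, evolves the signed matrix to a corner and
prints the classification report.  The synthetic group is built around a
CIII-like structure, so the pipeline recovers a CIII class graph.
"""

import tempfile
from pathlib import Path

import numpy as np

import signedbalance as sb

# synthetic nominations consistent with a CIII structure (3, 3, 1)
s = sb.make_template(sb.TemplateSpec("CIII", (3, 3, 1)))
rng = np.random.default_rng(0)
strength = rng.integers(1, 4, size=s.s.shape)  # nomination strengths 1..3
x_vals = np.where(s.s > 0, strength, 0)
y_vals = np.where(s.s < 0, strength, 0)


def to_dl(v: np.ndarray, labels: list[str]) -> str:
    rows = "\n".join(" ".join(str(int(x)) for x in row) for row in v)
    return (f"dl n={len(labels)}\nformat = fullmatrix\nlabels:\n"
            + ", ".join(labels) + "\ndata:\n" + rows + "\n")


labels = [f"actor{i}" for i in range(1, 8)]
with tempfile.TemporaryDirectory() as tmp:
    xp, yp = Path(tmp) / "X.dl", Path(tmp) / "Y.dl"
    xp.write_text(to_dl(x_vals, labels))
    yp.write_text(to_dl(y_vals, labels))
    x = sb.read_matrix(xp)
    y = sb.read_matrix(yp)

relations = sb.combine_signed(x, y, scale=5)
report = sb.analyze_sociomatrix(relations, origin=x.origin)
print(f"converged: {report.converged} at t = {report.t_end:.2f}")
print(f"class sizes: {report.graph.sizes}")
print(f"archetype:   {report.template.kind} {report.template.sizes}")
print(f"actors with F < 0 (1-based): {report.low_f_actors}")
# Actor 7 -- the rejected aspirant between the two hostile groups --
# carries the negative self-evaluation F = -3.
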