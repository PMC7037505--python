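"""Classify the fixed points of the mean-field replicator dynamics.

The two groups' evacuation shares (x, y) evolve by replicator dynamics
whose advantage functions are affine: UE1-US1 = A1*y + A2.  This script
prints the coefficients, every fixed point with its Jacobian determinant
and trace, and the stability label each earns.
"""

from evacgame import GroupEconomics, PolicyParams, field_coefficients, find_equilibria

coeffs = field_coefficients(GroupEconomics(), GroupEconomics(), PolicyParams())
print(
    f"advantage coefficients: A1={coeffs.A1:.4f}  A2={coeffs.A2:.4f}  "
    f"B1={coeffs.B1:.4f}  B2={coeffs.B2:.4f}"
)

report = find_equilibria(coeffs)
print(f"\n{'x':>8} {'y':>8} {'Det J':>10} {'Tr J':>10}  label")
for p in report.points:
    print(f"{p.x:8.4f} {p.y:8.4f} {p.detJ:10.4f} {p.trJ:10.4f}  {p.label}")

print(
    "\nThe interior point has trace exactly 0 and negative determinant: a"
    "\nsaddle.  The miscoordination corners (0,1)/(1,0) attract because"
    "\nevacuating pays exactly when the other group stays (A2 > 0 > A1+A2)."
)
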