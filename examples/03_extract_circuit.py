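"""Extract the minimal Boolean survival equation and draw the TIM circuit.

Thresholding a TIM at 0.5 yields a monotone Boolean function over target
inhibitions; its minimal effective terms are the smallest kinase
combinations predicted to kill the tumor, grouped into an AND/OR block
circuit for display.
"""

from timkit import TIM, group_blocks, minimal_equation, render_circuit

# survival map over PKCA, CDK4, PSMB5: the tumor dies when PKCA and CDK4
# are hit together, or when PSMB5 is hit alone
tim = TIM(
    members=(0, 1, 2),
    names=("PKCA", "CDK4", "PSMB5"),
    known={0b001: 0.15, 0b010: 0.20, 0b011: 0.92, 0b100: 0.88},
)

eq = minimal_equation(tim, theta_e=0.5, theta_i=0.5, max_term=3)
print("minimal effective terms:")
for term in eq.sorted_terms():
    print("  " + " AND ".join(eq.label(j) for j in term))

circuit = group_blocks(eq)
print("\nblocks (parallel lines must all be cut; any one block suffices):")
for i, block in enumerate(circuit.blocks):
    print(f"  block {i + 1}: " + "  |  ".join(" / ".join(line) for line in block))

print("\nDOT rendering:\n")
print(render_circuit(circuit))
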