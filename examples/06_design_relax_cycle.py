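"""Run the sequence-design / relax cycle with deterministic mock stages.

The orchestrator alternates binder sequence design (designer sees the
complex with the binder sequence masked) with whole-complex relaxation.
Mock stages stand in for an inverse-folding model and a relax program, so
this demonstrates the cycle contract, not real design.
"""

from binderscreen import (
    MockDesigner,
    MockRelaxer,
    build_prediction_request,
    make_toy_complex,
    mpnn_fr_cycle,
)

complex_ = make_toy_complex(binder_len=10, target_len=20, seed=0)
state = mpnn_fr_cycle(complex_, MockDesigner(seed=1), MockRelaxer(seed=2), n_cycles=3)

for entry in state.log:
    print(f"cycle {entry['iteration']}: seq={entry['sequence']} structure={entry['structure_id']}")
print(f"final binder sequence: {state.binder_sequence}")

request = build_prediction_request(state.structure)
print(f"prediction request: {request.n_positions} positions, "
      f"templated chains = {[c for c, t in request.target_template.items() if t]}")
# The final complex would be handed to a structure predictor seeded with
# these coordinates (initial-guess mode) and the target chain templated.
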