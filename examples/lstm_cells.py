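"""The LSTM cell, gate by gate, and its two hidden-update variants.

``standard`` applies tanh to the cell state in the hidden update
(a<t> = gate_o * tanh(c<t>)); ``strict_paper`` omits it
(a<t> = gate_o * c<t>), the form sometimes printed. The vectorized
training engine uses the standard form; both are compared against each
other and against the engine here.
"""

import numpy as np

from mannerkit.model import LSTMCellParams, LSTMState, lstm_cell_step
from mannerkit.model.network import _LSTMLayer
from mannerkit.model.reference import run_lstm_sequence

# Hand-checkable scalar cell: all weights zero, previous cell state 1.
params = LSTMCellParams.zeros(hidden_size=1, input_size=1)
state = LSTMState(a=np.zeros(1), c=np.ones(1))
std = lstm_cell_step(np.zeros(1), state, params, mode="standard")
strict = lstm_cell_step(np.zeros(1), state, params, mode="strict_paper")
print("zero-weight cell, c<t-1>=1: gates sigmoid(0)=0.5, candidate tanh(0)=0")
print(f"  c<t> = 0.5*0 + 0.5*1          = {std.c[0]:.4f}")
print(f"  a<t> standard     (0.5*tanh(c)) = {std.a[0]:.4f}")
print(f"  a<t> strict_paper (0.5*c)       = {strict.a[0]:.4f}")

# Engine equivalence: the fused-gate training cell and the per-gate
# reference cell compute the same trajectory.
rng = np.random.default_rng(0)
layer = _LSTMLayer(input_size=6, hidden_size=5, rng=rng)
xs = rng.normal(size=(10, 6))
engine, _ = layer.forward(xs[None])
reference = run_lstm_sequence(xs, layer.cell_params(), mode="standard")
print(f"engine vs reference max |diff| over 10 steps: "
      f"{np.abs(engine[0] - reference).max():.2e}")
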