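"""Reference recurrent cells, written gate by gate.

These are pedagogical, equation-level implementations kept independent of
the vectorized training engine in :mod:`mannerkit.model.network`; tests
cross-check the two. The LSTM cell supports two variants of the hidden
update:

* ``standard``: ``a<t> = gate_o * tanh(c<t>)`` — the conventional cell,
  and what mainstream deep-learning toolkits compute;
* ``strict_paper``: ``a<t> = gate_o * c<t>`` — the update as sometimes
  printed with the tanh on the cell state omitted, preserved here for
  fidelity testing.

All gates act on the concatenation ``[a<t-1>, x<t>]``; ``a<0>`` and
``c<0>`` are zero vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ValidationError


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Logistic function 1 / (1 + e^-x), scaling inputs into (0, 1)."""
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class LSTMState:
    """Hidden state ``a<t>`` and cell state ``c<t>`` of equal length."""

    a: np.ndarray
    c: np.ndarray

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.a.shape != self.c.shape:
            raise ValidationError("hidden and cell state must have equal shape")

    @classmethod
    def zeros(cls, hidden_size: int) -> "LSTMState":
        return cls(np.zeros(hidden_size), np.zeros(hidden_size))


@dataclass
class LSTMCellParams:
    """Per-gate weights over ``[a<t-1>, x<t>]`` and biases.

    Each ``w_*`` has shape ``(hidden, hidden + input)``; each ``b_*`` has
    shape ``(hidden,)``. Gates: update (input) gate, forget gate, output
    gate, and the candidate cell value.
    """

    w_update: np.ndarray
    b_update: np.ndarray
    w_forget: np.ndarray
    b_forget: np.ndarray
    w_output: np.ndarray
    b_output: np.ndarray
    w_candidate: np.ndarray
    b_candidate: np.ndarray

    def __post_init__(self):
        shapes = {
            np.asarray(w).shape
            for w in (self.w_update, self.w_forget, self.w_output, self.w_candidate)
        }
        if len(shapes) != 1:
            raise ValidationError("gate weight matrices must share one shape")
        (h, hi) = shapes.pop()
        for b in (self.b_update, self.b_forget, self.b_output, self.b_candidate):
            if np.asarray(b).shape != (h,):
                raise ValidationError("gate biases must have shape (hidden,)")
        if not all(
            np.all(np.isfinite(m))
            for m in (self.w_update, self.w_forget, self.w_output, self.w_candidate,
                      self.b_update, self.b_forget, self.b_output, self.b_candidate)
        ):
            raise ValidationError("cell parameters must be finite")
        self.hidden_size = h
        self.input_size = hi - h

    @classmethod
    def zeros(cls, hidden_size: int, input_size: int) -> "LSTMCellParams":
        w = np.zeros((hidden_size, hidden_size + input_size))
        b = np.zeros(hidden_size)
        return cls(w.copy(), b.copy(), w.copy(), b.copy(),
                   w.copy(), b.copy(), w.copy(), b.copy())


def rnn_cell_step(
    x: np.ndarray,
    a_prev: np.ndarray,
    W: np.ndarray,
    ba: np.ndarray,
    Wy: np.ndarray,
    by: np.ndarray,
    g=np.tanh,
) -> tuple[np.ndarray, np.ndarray]:
    """One plain recurrent cell step.

    ``a<t> = g(W [a<t-1>; x<t>] + ba)`` and ``y<t> = g(Wy a<t> + by)``.
    ``W`` has shape ``(hidden, hidden + input)``. Updates run
    sequentially from ``a<0> = 0``.
    """
    x = np.asarray(x, dtype=float)
    a_prev = np.asarray(a_prev, dtype=float)
    concat = np.concatenate([a_prev, x])
    if W.shape[1] != concat.size:
        raise ValidationError(
            f"W has {W.shape[1]} columns but [a, x] has length {concat.size}"
        )
    a = g(W @ concat + ba)
    y = g(Wy @ a + by)
    return a, y


def lstm_cell_step(
    x: np.ndarray,
    state: LSTMState,
    params: LSTMCellParams,
    mode: str = "standard",
) -> LSTMState:
    """One LSTM cell step, gate by gate.

    With ``z = [a<t-1>; x<t>]``::

        gate_u = sigmoid(Wu z + bu)        (update gate)
        gate_f = sigmoid(Wf z + bf)        (forget gate)
        gate_o = sigmoid(Wo z + bo)        (output gate)
        c_cand = tanh(Wc z + bc)           (candidate cell value)
        c<t>   = gate_u * c_cand + gate_f * c<t-1>
        a<t>   = gate_o * tanh(c<t>)       (standard mode)
        a<t>   = gate_o * c<t>             (strict_paper mode)

    ``*`` is the element-wise product.
    """
    if mode not in ("standard", "strict_paper"):
        raise ValidationError(f"unknown mode {mode!r}")
    x = np.asarray(x, dtype=float)
    if x.size != params.input_size:
        raise ValidationError(
            f"input has length {x.size}, cell expects {params.input_size}"
        )
    if state.a.size != params.hidden_size:
        raise ValidationError(
            f"state has length {state.a.size}, cell expects {params.hidden_size}"
        )
    z = np.concatenate([state.a, x])
    gate_u = sigmoid(params.w_update @ z + params.b_update)
    gate_f = sigmoid(params.w_forget @ z + params.b_forget)
    gate_o = sigmoid(params.w_output @ z + params.b_output)
    c_cand = np.tanh(params.w_candidate @ z + params.b_candidate)
    c = gate_u * c_cand + gate_f * state.c
    if mode == "standard":
        a = gate_o * np.tanh(c)
    else:
        a = gate_o * c
    return LSTMState(a=a, c=c)


def run_lstm_sequence(
    xs: np.ndarray,
    params: LSTMCellParams,
    mode: str = "standard",
) -> np.ndarray:
    """Run the reference cell over a ``(T, input)`` sequence from zero
    state; returns the ``(T, hidden)`` hidden-state trajectory."""
    state = LSTMState.zeros(params.hidden_size)
    out = np.empty((len(xs), params.hidden_size))
    for t, x in enumerate(xs):
        state = lstm_cell_step(x, state, params, mode)
        out[t] = state.a
    return out
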