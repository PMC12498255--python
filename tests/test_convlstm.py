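"""ConvLSTM cell vs a scalar peephole-LSTM oracle, stack and branch contracts."""

import math

import numpy as np
import pytest

from trunet.convlstm import (CellState, ConvLSTMCell, ConvLSTMStack,
                             TemporalBranch, convlstm_step)
from trunet.nn.tensor import Tensor


def scalar_peephole_lstm(xs, p):
    """Pure-python peephole LSTM recursion; the independent oracle.

    The output gate peeps at the *new* cell state.
    """
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    h = c = 0.0
    for x in xs:
        f = sig(p["wxf"] * x + p["whf"] * h + p["wcf"] * c + p["bf"])
        i = sig(p["wxi"] * x + p["whi"] * h + p["wci"] * c + p["bi"])
        g = math.tanh(p["wxc"] * x + p["whc"] * h + p["bc"])
        c = f * c + i * g
        o = sig(p["wxo"] * x + p["who"] * h + p["wco"] * c + p["bo"])
        h = o * math.tanh(c)
    return h, c


def scalar_cell(params) -> ConvLSTMCell:
    """1-channel, 1x1-kernel cell wired with the given scalar parameters."""
    cell = ConvLSTMCell(1, 1, kernel=1, rng=np.random.default_rng(0),
                        dtype=np.float64)
    for name in ("wxf", "whf", "wxi", "whi", "wxc", "whc", "wxo", "who"):
        getattr(cell, name).weight.data[:] = params[name]
    for name in ("wcf", "wci", "wco", "bf", "bi", "bc", "bo"):
        getattr(cell, name).data[:] = params[name]
    return cell


PARAM_NAMES = ("wxf", "whf", "wcf", "bf", "wxi", "whi", "wci", "bi",
               "wxc", "whc", "bc", "wxo", "who", "wco", "bo")


def random_params(rng):
    return {k: float(rng.uniform(-1.5, 1.5)) for k in PARAM_NAMES}


def test_step_matches_scalar_oracle_100_trials():
    rng = np.random.default_rng(0)
    for _ in range(100):
        p = random_params(rng)
        cell = scalar_cell(p)
        x = float(rng.uniform(-2, 2))
        h, state = convlstm_step(np.array([[[[x]]]]), CellState.zeros(1, 1, (1, 1),
                                                                     np.float64), cell)
        h_ref, c_ref = scalar_peephole_lstm([x], p)
        assert abs(h.data[0, 0, 0, 0] - h_ref) <= 1e-10
        assert abs(state.c.data[0, 0, 0, 0] - c_ref) <= 1e-10


def test_run_sequence_matches_scalar_oracle_any_T():
    rng = np.random.default_rng(1)
    for T in (1, 2, 3, 5, 8):
        p = random_params(rng)
        cell = scalar_cell(p)
        stack = ConvLSTMStack(1, 1, layers=1, kernel=1, dtype=np.float64)
        stack.cells[0] = cell
        xs = [float(rng.uniform(-2, 2)) for _ in range(T)]
        out = stack.run_sequence([np.array([[[[x]]]], dtype=np.float64) for x in xs])
        h_ref, _ = scalar_peephole_lstm(xs, p)
        assert abs(out.data[0, 0, 0, 0] - h_ref) <= 1e-8


def test_zero_weights_zero_state_is_fixed_point(rng):
    cell = ConvLSTMCell(2, 3, rng=np.random.default_rng(0), dtype=np.float64)
    for p in cell.parameters():
        p.data[:] = 0.0
    x = rng.standard_normal((1, 2, 4, 4))
    h, state = cell(Tensor(x), CellState.zeros(1, 3, (4, 4), np.float64))
    assert np.all(h.data == 0)
    assert np.all(state.c.data == 0)


def test_saturated_gates_carry_memory():
    # f ~= 1, i ~= 0  =>  c' ~= c regardless of the input
    p = {k: 0.3 for k in PARAM_NAMES}
    p.update(bf=20.0, bi=-20.0)
    cell = scalar_cell(p)
    c0 = 0.7
    state = CellState(Tensor(np.zeros((1, 1, 1, 1))),
                      Tensor(np.full((1, 1, 1, 1), c0)))
    _, new = cell(Tensor(np.array([[[[1.3]]]])), state)
    assert abs(new.c.data.item() - c0) < 1e-6


def test_gate_ranges_bound_states(rng):
    cell = ConvLSTMCell(2, 4, rng=np.random.default_rng(3), dtype=np.float64)
    state = CellState.zeros(2, 4, (6, 6), np.float64)
    for step in range(5):
        x = Tensor(rng.standard_normal((2, 2, 6, 6)) * 3)
        prev_c = state.c.data.copy()
        h, state = cell(x, state)
        assert np.all(np.abs(state.c.data) <= np.abs(prev_c) + 1.0 + 1e-12)
        assert np.all(np.abs(h.data) < 1.0)
        assert h.shape[2:] == (6, 6)  # same-padding keeps spatial size


def test_sequence_order_sensitivity(rng):
    hits = 0
    for trial in range(10):
        stack = ConvLSTMStack(1, 2, layers=2, rng=np.random.default_rng(trial),
                              dtype=np.float64)
        xs = [rng.standard_normal((1, 1, 5, 5)) for _ in range(3)]
        fwd = stack.run_sequence(xs).data
        rev = stack.run_sequence(xs[::-1]).data
        if np.abs(fwd - rev).max() > 0:
            hits += 1
    assert hits == 10


def test_state_accumulates_with_length(rng):
    stack = ConvLSTMStack(1, 2, layers=1, rng=np.random.default_rng(5),
                          dtype=np.float64)
    x = rng.standard_normal((1, 1, 4, 4))
    out2 = stack.run_sequence([x, x]).data
    out3 = stack.run_sequence([x, x, x]).data
    assert np.abs(out2 - out3).max() > 0


def test_run_sequence_T1_equals_single_step(rng):
    stack = ConvLSTMStack(2, 3, layers=1, rng=np.random.default_rng(6),
                          dtype=np.float64)
    x = rng.standard_normal((1, 2, 4, 4))
    out = stack.run_sequence([x]).data
    h, _ = stack.cells[0](Tensor(x), CellState.zeros(1, 3, (4, 4), np.float64))
    assert np.array_equal(out, h.data)


def test_empty_sequence_and_shape_mismatch_rejected(rng):
    stack = ConvLSTMStack(1, 2, rng=np.random.default_rng(7))
    with pytest.raises(ValueError):
        stack.run_sequence([])
    cell = ConvLSTMCell(1, 2, rng=np.random.default_rng(8))
    with pytest.raises(ValueError):
        cell(Tensor(np.zeros((1, 1, 4, 4))), CellState.zeros(1, 2, (6, 6)))


# -- temporal branch --------------------------------------------------------

def make_branch(skip_channels, dtype=np.float64):
    return TemporalBranch(stem_width=3, hidden=4, layers=2, head_widths=(6, 5),
                          skip_channels=skip_channels, grid=8,
                          rng=np.random.default_rng(0), dtype=dtype)


def test_branch_scale_and_channel_contract(rng):
    branch = make_branch({4: 7, 8: 9})
    branch.eval()
    xs = [rng.standard_normal((2, 1, 64, 64)) for _ in range(3)]
    out = branch(xs)
    assert out[4].shape == (2, 7, 16, 16)
    assert out[8].shape == (2, 9, 8, 8)


def test_branch_zero_input_zero_output_with_zero_biases(rng):
    branch = make_branch({4: 5})
    branch.eval()   # BN in eval mode: zero running mean, unit variance
    out = branch([np.zeros((1, 1, 64, 64)) for _ in range(3)])
    assert np.abs(out[4].data).max() == 0.0


def test_branch_unreachable_scale_rejected(rng):
    branch = make_branch({4: 5})
    xs = [rng.standard_normal((1, 1, 64, 60)) for _ in range(3)]
    with pytest.raises(ValueError):
        branch(xs)
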