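"""Compiled trial kernel.

The numba kernel replays exactly the arithmetic of the reference
numpy step loop in :mod:`plastnet.dynamics` — same snapshot semantics,
same delivery accumulation order — so that both engines produce
bit-identical trajectories (asserted by the test suite).  When numba is
unavailable the package transparently falls back to the numpy loop.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _trial_kernel(
    indptr,
    syn_post,
    weights,
    sign,
    v,
    out_id,
    v_max,
    delta_eta,
    t_refr,
    linear,
    same_step_block,
    step_cap,
    n_act,
    fire_t,
    fire_id,
):
    n = v.shape[0]
    eta = np.ones(n)
    refr = np.zeros(n, dtype=np.int64)
    fired = np.empty(n, dtype=np.int64)
    base = np.empty(n)
    dv = np.empty(n)
    is_firing = np.zeros(n, dtype=np.bool_)
    t = 0
    nf = 0
    output_fired = False
    out_changed = False

    while True:
        m = 0
        for i in range(n):
            if refr[i] == 0 and v[i] >= v_max:
                fired[m] = i
                is_firing[i] = True
                m += 1
        if m == 0:
            break
        if t >= step_cap:
            return n_act, nf, output_fired, out_changed, t, True

        # snapshot transmitted amounts before any delivery or reset
        for k in range(m):
            i = fired[k]
            b = sign[i] * eta[i]
            if linear:
                b = b * v[i]
            base[i] = b
        for j in range(n):
            dv[j] = 0.0
        for k in range(m):
            i = fired[k]
            for s in range(indptr[i], indptr[i + 1]):
                j = syn_post[s]
                if refr[j] > 0:
                    continue
                if same_step_block and t_refr > 0 and is_firing[j]:
                    continue
                n_act[s] += 1
                dv[j] += weights[s] * base[i]
                if j == out_id:
                    out_changed = True
        # reset fired potentials first: simultaneous deliveries to a
        # firing neuron land on the cleared potential and persist
        for k in range(m):
            v[fired[k]] = 0.0
        for j in range(n):
            v[j] += dv[j]
        for k in range(m):
            i = fired[k]
            e = eta[i] - delta_eta
            eta[i] = e if e > 0.0 else 0.0
            fire_t[nf] = t
            fire_id[nf] = i
            nf += 1
            if i == out_id:
                output_fired = True
        for j in range(n):
            if refr[j] > 0:
                refr[j] -= 1
        for k in range(m):
            refr[fired[k]] = t_refr
            is_firing[fired[k]] = False
        t += 1

    return n_act, nf, output_fired, out_changed, t, False


def run_trial_numba(net, pattern, cfg, step_cap):
    """Run one trial through the compiled kernel; returns a TrialRecord."""
    from .dynamics import LINEAR, SimulationDivergenceError, TrialRecord

    n = net.n_neurons
    pattern = np.asarray(pattern, dtype=int)
    inputs = net.input_ids
    if pattern.shape != (len(inputs),):
        raise ValueError(
            f"pattern must have {len(inputs)} bits, got shape {pattern.shape}"
        )
    v = np.zeros(n)
    v[inputs[pattern == 1]] = cfg.v_max
    sign = np.where(net.inhibitory, -1.0, 1.0)
    n_act = np.zeros(net.n_synapses, dtype=np.int64)
    # deliveries require a transmitter-bearing firing (<= ceil(1/dn)
    # per neuron), and every firing needs a delivery, so this bounds
    # the firing log
    cap_f = (int(np.ceil(1.0 / cfg.delta_eta)) + 1) * max(net.n_synapses, n) + n + 8
    fire_t = np.empty(cap_f, dtype=np.int64)
    fire_id = np.empty(cap_f, dtype=np.int64)

    n_act, nf, output_fired, out_changed, duration, diverged = _trial_kernel(
        net.indptr,
        net.syn_post,
        net.weights,
        sign,
        v,
        net.output_id,
        cfg.v_max,
        cfg.delta_eta,
        cfg.t_refr,
        cfg.activation == LINEAR,
        cfg.refr_same_step,
        step_cap,
        n_act,
        fire_t,
        fire_id,
    )
    if diverged:
        raise SimulationDivergenceError(
            f"trial exceeded step cap {step_cap}; activity should "
            "terminate under transmitter depletion"
        )
    firings = np.column_stack((fire_t[:nf], fire_id[:nf]))
    return TrialRecord(
        output_fired=bool(output_fired),
        output_voltage_changed=bool(out_changed),
        n_act=n_act,
        firings=firings,
        duration=int(duration),
    )
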