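"""Numba-compiled inner loop of the clock-driven simulator.

One kernel advances the whole heterogeneous circuit (LIF units and
rate-modulated Poisson units) on a fixed dt grid, including synaptic delay
propagation through a ring buffer, exponential rate traces, the dopamine
trace with its trailing-window baseline, and in-step plasticity updates.
All state lives in flat numpy arrays owned by the Python-side ``Network``;
the kernel is restartable mid-chunk so spike buffers can be regrown.
"""

import numpy as np
from numba import njit

KIND_LIF = 0
KIND_POISSON = 1

RULE_HEBBIAN = 0
RULE_THREE_FACTOR = 1

_INV_2_53 = 1.0 / 9007199254740992.0


@njit(cache=True, inline="always")
def _rng_uniform(state):
    # splitmix64 counter stream: deterministic, platform-stable, cheap.
    state[0] = state[0] + np.uint64(0x9E3779B97F4A7C15)
    z = state[0]
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    return (z >> np.uint64(11)) * _INV_2_53


@njit(cache=True)
def run_chunk(
    n_steps,
    start_step,
    dt,
    # unit model arrays
    kind,
    e_m,
    dv_gain,
    e_s,
    v_th,
    v_reset,
    ref_steps,
    i_bias,
    rate_base,
    rate_gain,
    # unit state arrays
    V,
    I_syn,
    ref_until,
    F,
    e_F,
    f_incr,
    ring,
    # connectivity (CSR by presynaptic unit)
    indptr,
    post,
    weight,
    delay,
    # plasticity
    plast_interval,
    pe_idx,
    pe_pre,
    pe_post,
    pe_group,
    pg_rule,
    pg_mu,
    pg_kappa,
    pg_ft,
    pg_wmin,
    pg_wmax,
    # dopamine trace + baseline ring buffer
    d_pop,
    d_gain,
    d_offset,
    d_sample_steps,
    d_ring,
    d_state,
    # recorders
    rec_mask,
    sp_unit,
    sp_step,
    rec_interval,
    rec_units,
    rec_buf,
    rec_row0,
    drec_buf,
    drec_row0,
    # scratch + rng
    step_spk,
    rng_state,
):
    """Advance the network by up to ``n_steps`` steps.

    Returns (steps_done, n_spikes_recorded).  steps_done < n_steps only
    when the spike buffer is close to capacity; the caller regrows the
    buffer and resumes from start_step + steps_done.
    """
    n = kind.shape[0]
    ring_len = ring.shape[0]
    cap = sp_unit.shape[0]
    n_sp = 0
    dt_s = dt * 1e-3
    for s in range(n_steps):
        if n_sp + n > cap:
            return s, n_sp
        abs_step = start_step + s
        cur = abs_step % ring_len
        k = 0
        for u in range(n):
            I = I_syn[u] * e_s[u] + ring[cur, u]
            ring[cur, u] = 0.0
            I_syn[u] = I
            if kind[u] == KIND_LIF:
                if abs_step >= ref_until[u]:
                    v = V[u] * e_m[u] + (I + i_bias[u]) * dv_gain[u]
                    if v >= v_th[u]:
                        V[u] = v_reset[u]
                        ref_until[u] = abs_step + 1 + ref_steps[u]
                        step_spk[k] = u
                        k += 1
                    else:
                        V[u] = v
            else:
                lam = rate_base[u] + rate_gain[u] * I
                if lam > 0.0 and _rng_uniform(rng_state) < lam * dt_s:
                    step_spk[k] = u
                    k += 1
        for u in range(n):
            F[u] *= e_F
        for j in range(k):
            u = step_spk[j]
            F[u] += f_incr
            if rec_mask[u]:
                sp_unit[n_sp] = u
                sp_step[n_sp] = abs_step
                n_sp += 1
            for e in range(indptr[u], indptr[u + 1]):
                ring[(cur + delay[e]) % ring_len, post[e]] += weight[e]
        t1 = abs_step + 1
        if d_sample_steps > 0 and t1 % d_sample_steps == 0:
            acc = 0.0
            for j in range(d_pop.shape[0]):
                acc += F[d_pop[j]]
            if d_pop.shape[0] > 0:
                acc /= d_pop.shape[0]
            Dv = d_gain * acc + d_offset
            pos = int(d_state[0])
            cnt = int(d_state[1])
            if cnt < d_ring.shape[0]:
                d_state[2] += Dv
                cnt += 1
            else:
                d_state[2] += Dv - d_ring[pos]
            d_ring[pos] = Dv
            d_state[0] = (pos + 1) % d_ring.shape[0]
            d_state[1] = cnt
            d_state[3] = Dv
            d_state[4] = d_state[2] / cnt
            if drec_buf.shape[0] > 0:
                row = t1 // d_sample_steps - 1 - drec_row0
                if row >= 0 and row < drec_buf.shape[0]:
                    drec_buf[row, 0] = Dv
                    drec_buf[row, 1] = d_state[4]
        if plast_interval > 0 and t1 % plast_interval == 0:
            Dcur = d_state[3]
            bD = d_state[4]
            for i in range(pe_idx.shape[0]):
                g = pe_group[i]
                fi = F[pe_pre[i]]
                fj = F[pe_post[i]]
                w = weight[pe_idx[i]]
                hebb = fi * fj
                if pg_rule[g] == RULE_THREE_FACTOR:
                    hebb = (Dcur - bD) * hebb
                w2 = w + pg_mu[g] * (hebb + pg_kappa[g] * (pg_ft[g] - fj) * w * w)
                if w2 < pg_wmin[g]:
                    w2 = pg_wmin[g]
                elif w2 > pg_wmax[g]:
                    w2 = pg_wmax[g]
                weight[pe_idx[i]] = w2
        if rec_interval > 0 and t1 % rec_interval == 0:
            row = t1 // rec_interval - 1 - rec_row0
            if row >= 0 and row < rec_buf.shape[0]:
                for j in range(rec_units.shape[0]):
                    rec_buf[row, j] = F[rec_units[j]]
    return n_steps, n_sp
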