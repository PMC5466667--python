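"""Direct-method SSA kernel, written to be numba-njit compatible.

The same source runs as plain Python (slow, used when numba is missing or
explicitly requested) or JIT-compiled.  All channel propensities are
recomputed after every firing because every one of them depends on the
isotonic volume and the surface area, which change at every step.

Channel layout: reactions [0, n_rxn), then per-species transport pairs
(influx, efflux), then the four membrane-exchange channels (l uptake,
l release, L insertion, L->l displacement).

Outcome codes: 0 horizon reached, 1 burst, 2 event budget exhausted,
3 division budget exhausted, 4 internal inconsistency (negative count).
"""

from __future__ import annotations

import math

import numpy as np

OUT_OK = 0
OUT_BURST = 1
OUT_MAX_EVENTS = 2
OUT_MAX_DIV = 3
OUT_ERROR = 4


def _curve_eval(chi, xs, ws, fs):
    n = xs.shape[0]
    for i in range(n):
        if chi == xs[i]:
            return fs[i]
    num = 0.0
    den = 0.0
    for i in range(n):
        t = ws[i] / (chi - xs[i])
        num += t * fs[i]
        den += t
    return num / den


def _direct_ssa(
    N,
    n_l,
    n_L,
    osmotic,
    perm_coeff,
    perm_compdep,
    env_conc,
    stoich,
    react_idx,
    cat_idx,
    rate_k,
    rxn_order,
    alpha_l,
    alpha_L,
    u_l,
    k_out,
    k_ins,
    k_d,
    iL,
    c_out,
    na,
    phi_divide,
    phi_burst,
    curve_x,
    curve_w,
    curve_f,
    use_curve,
    t_end,
    sample_times,
    seed,
    max_events,
    protocell,
    V_fixed,
    S_fixed,
    max_div,
):
    np.random.seed(seed)
    n_sp = N.shape[0]
    n_rxn = rate_k.shape[0]
    n_chan = n_rxn + 2 * n_sp + 4
    a = np.zeros(n_chan)
    n_t = sample_times.shape[0]
    samples = np.zeros((n_t, n_sp + 2))
    div_t = np.zeros(max_div)
    div_stats = np.zeros((max_div, 4))  # T_div, chi, V, S at division
    div_counts = np.zeros((max_div, n_sp + 2))  # mother, pre-partition
    div_kept = np.zeros((max_div, n_sp + 2))  # followed daughter, post-partition
    n_div = 0
    t = 0.0
    t_last_div = 0.0
    sample_ptr = 0
    n_events = 0
    max_iso_dev = 0.0
    outcome = OUT_OK

    while True:
        # geometry
        tot_osm = 0.0
        for i in range(n_sp):
            tot_osm += osmotic[i] * N[i]
        if protocell:
            V = tot_osm / (na * c_out)
            S = 0.5 * (n_l * alpha_l + n_L * alpha_L)
            c_tot = tot_osm / (V * na)
            dev = abs(c_tot - c_out) / c_out
            if dev > max_iso_dev:
                max_iso_dev = dev
        else:
            V = V_fixed
            S = S_fixed
        area = n_l * alpha_l + n_L * alpha_L
        chi = n_L * alpha_L / area if area > 0.0 else 0.0
        f = _curve_eval(chi, curve_x, curve_w, curve_f) if use_curve else 1.0

        # events (protocell mode only)
        if protocell:
            phi = S / (36.0 * math.pi * V * V) ** (1.0 / 3.0)
            if phi <= phi_burst:
                outcome = OUT_BURST
                break
            if phi >= phi_divide:
                # record mother, then keep one binomially partitioned daughter
                if n_div >= max_div:
                    outcome = OUT_MAX_DIV
                    break
                div_t[n_div] = t
                div_stats[n_div, 0] = t - t_last_div
                div_stats[n_div, 1] = chi
                div_stats[n_div, 2] = V
                div_stats[n_div, 3] = S
                for i in range(n_sp):
                    div_counts[n_div, i] = N[i]
                div_counts[n_div, n_sp] = n_l
                div_counts[n_div, n_sp + 1] = n_L
                t_last_div = t
                for i in range(n_sp):
                    if N[i] > 0:
                        N[i] = np.random.binomial(N[i], 0.5)
                half = n_l // 2
                if n_l % 2 == 1 and np.random.random() < 0.5:
                    half += 1
                n_l = half
                half = n_L // 2
                if n_L % 2 == 1 and np.random.random() < 0.5:
                    half += 1
                n_L = half
                for i in range(n_sp):
                    div_kept[n_div, i] = N[i]
                div_kept[n_div, n_sp] = n_l
                div_kept[n_div, n_sp + 1] = n_L
                n_div += 1
                continue  # re-enter with fresh geometry

        # propensities (per hour)
        vna = V * na
        for j in range(n_rxn):
            aj = rate_k[j]
            for s in range(react_idx.shape[1]):
                i = react_idx[j, s]
                if i >= 0:
                    aj *= N[i]
            ci = cat_idx[j]
            if ci >= 0:
                aj *= N[ci]
            order = rxn_order[j]
            for _ in range(order - 1):
                aj /= vna
            a[j] = aj
        for i in range(n_sp):
            p = perm_coeff[i]
            if p > 0.0 and perm_compdep[i] == 1:
                p *= f
            a[n_rxn + 2 * i] = p * S * env_conc[i] * na
            a[n_rxn + 2 * i + 1] = p * S * N[i] / V
        base = n_rxn + 2 * n_sp
        if protocell:
            a[base] = u_l * S
            a[base + 1] = k_out * n_l
            a[base + 2] = k_ins * S * N[iL] / V if iL >= 0 else 0.0
            a[base + 3] = k_d * n_L
        else:
            a[base] = 0.0
            a[base + 1] = 0.0
            a[base + 2] = 0.0
            a[base + 3] = 0.0

        a_tot = 0.0
        for k in range(n_chan):
            a_tot += a[k]

        if a_tot <= 0.0:
            t_next = t_end + 1.0
        else:
            t_next = t - math.log(np.random.random()) / a_tot

        while sample_ptr < n_t and sample_times[sample_ptr] <= min(t_next, t_end):
            for i in range(n_sp):
                samples[sample_ptr, i] = N[i]
            samples[sample_ptr, n_sp] = n_l
            samples[sample_ptr, n_sp + 1] = n_L
            sample_ptr += 1

        if t_next > t_end:
            t = t_end
            break
        t = t_next

        # pick channel
        r = np.random.random() * a_tot
        acc = 0.0
        chosen = n_chan - 1
        for k in range(n_chan):
            acc += a[k]
            if r <= acc:
                chosen = k
                break

        if chosen < n_rxn:
            for i in range(n_sp):
                N[i] += stoich[chosen, i]
        elif chosen < n_rxn + 2 * n_sp:
            i = (chosen - n_rxn) // 2
            if (chosen - n_rxn) % 2 == 0:
                N[i] += 1
            else:
                N[i] -= 1
        else:
            lc = chosen - base
            if lc == 0:
                n_l += 1
            elif lc == 1:
                n_l -= 1
            elif lc == 2:
                N[iL] -= 1
                n_L += 1
            else:
                n_L -= 1
                n_l += 1

        for i in range(n_sp):
            if N[i] < 0:
                outcome = OUT_ERROR
                break
        if outcome == OUT_ERROR or n_l < 0 or n_L < 0:
            outcome = OUT_ERROR
            break

        n_events += 1
        if n_events >= max_events:
            outcome = OUT_MAX_EVENTS
            break

    # fill any remaining sample slots with the final state
    while sample_ptr < n_t:
        for i in range(n_sp):
            samples[sample_ptr, i] = N[i]
        samples[sample_ptr, n_sp] = n_l
        samples[sample_ptr, n_sp + 1] = n_L
        sample_ptr += 1

    return (
        samples,
        outcome,
        n_events,
        max_iso_dev,
        div_t,
        div_stats,
        div_counts,
        div_kept,
        n_div,
        t,
    )


direct_ssa_py = _direct_ssa

try:  # pragma: no cover - exercised implicitly
    import numba

    # rebind the module-global curve evaluator so the jitted kernel sees a
    # jitted callee; the python path happily calls the jitted version too
    _curve_eval = numba.njit(cache=True)(_curve_eval)
    direct_ssa_jit = numba.njit(cache=True)(_direct_ssa)
except ImportError:  # pragma: no cover
    direct_ssa_jit = None
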