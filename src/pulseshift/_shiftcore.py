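"""Numba-compiled kernels for the rate-shift sampler.

The state of the sampler is a flat representation of a shift configuration:
``k`` shifts stored in parallel arrays (branch id, offset from the branch's
rootward end, initial rate beta, rate-change exponent b) plus the root
regime.  Each regime's instantaneous rate is
``beta_init * exp(b * (t - t_regime_start))`` in absolute time t since the
root; a branch's accumulated variance is the integral of that rate over its
regime segments, which reduces the multi-regime BM likelihood to a standard
independent-contrasts REML evaluation on "effective" branch lengths.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _integral(beta, b, ts, a, c):
    """Integral of beta*exp(b*(t-ts)) over [a, c]; second-order series near
    b = 0 to avoid catastrophic cancellation."""
    if abs(b) * (abs(c - ts) + abs(a - ts)) < 1e-8:
        return beta * ((c - a) + 0.5 * b * ((c - ts) ** 2 - (a - ts) ** 2))
    return beta * (math.exp(b * (c - ts)) - math.exp(b * (a - ts))) / b


@njit(cache=True)
def _effective_lengths(
    parent, preorder, t0, t1,
    k, sbr, spos, sbeta, sb,
    root_beta, root_b,
    eff, reg_beta, reg_b, reg_ts,
):
    root = preorder[0]
    reg_beta[root] = root_beta
    reg_b[root] = root_b
    reg_ts[root] = 0.0
    eff[root] = 0.0
    for ii in range(1, preorder.shape[0]):
        v = preorder[ii]
        p = parent[v]
        beta = reg_beta[p]
        b = reg_b[p]
        ts = reg_ts[p]
        a = t0[v]
        end = t1[v]
        cnt = 0
        for s in range(k):
            if sbr[s] == v:
                cnt += 1
        tot = 0.0
        if cnt == 0:
            tot = _integral(beta, b, ts, a, end)
        else:
            idxs = np.empty(cnt, np.int64)
            m = 0
            for s in range(k):
                if sbr[s] == v:
                    idxs[m] = s
                    m += 1
            for i in range(1, cnt):
                key = idxs[i]
                j = i - 1
                while j >= 0 and spos[idxs[j]] > spos[key]:
                    idxs[j + 1] = idxs[j]
                    j -= 1
                idxs[j + 1] = key
            cur = a
            for i in range(cnt):
                st = a + spos[idxs[i]]
                tot += _integral(beta, b, ts, cur, st)
                beta = sbeta[idxs[i]]
                b = sb[idxs[i]]
                ts = st
                cur = st
            tot += _integral(beta, b, ts, cur, end)
        eff[v] = tot
        reg_beta[v] = beta
        reg_b[v] = b
        reg_ts[v] = ts


@njit(cache=True)
def _reml_bm(postorder, child_list, child_ptr, eff, values, tip_var, xw, vw):
    """REML (independent contrasts) log-likelihood of unit-rate BM on branch
    variances ``eff`` with ``tip_var`` added at tips."""
    ll = 0.0
    for ii in range(postorder.shape[0]):
        node = postorder[ii]
        c0 = child_ptr[node]
        c1 = child_ptr[node + 1]
        if c1 == c0:
            xw[node] = values[node]
            vw[node] = eff[node] + tip_var
            continue
        c = child_list[c0]
        X = xw[c]
        V = vw[c]
        for i in range(c0 + 1, c1):
            c = child_list[i]
            s = V + vw[c]
            d = X - xw[c]
            ll += -0.5 * (math.log(2.0 * math.pi * s) + d * d / s)
            X = (X * vw[c] + xw[c] * V) / s
            V = V * vw[c] / s
        xw[node] = X
        vw[node] = V + eff[node]
    return ll


@njit(cache=True)
def _loglik(
    parent, preorder, postorder, child_list, child_ptr, t0, t1,
    k, sbr, spos, sbeta, sb, root_beta, root_b,
    values, tip_var, eff, reg_beta, reg_b, reg_ts, xw, vw,
):
    _effective_lengths(
        parent, preorder, t0, t1, k, sbr, spos, sbeta, sb,
        root_beta, root_b, eff, reg_beta, reg_b, reg_ts,
    )
    return _reml_bm(postorder, child_list, child_ptr, eff, values, tip_var, xw, vw)


@njit(cache=True)
def _log_prior(
    k, sbeta, sb, root_beta, root_b,
    gamma, total_len, mulog, sdlog, sdb, b_free,
):
    lp = k * math.log(gamma) - gamma - math.lgamma(k + 1.0)
    lp += -k * math.log(total_len)
    x = math.log(root_beta)
    lp += -x - math.log(sdlog) - 0.5 * math.log(2.0 * math.pi)
    lp += -((x - mulog) ** 2) / (2.0 * sdlog**2)
    for s in range(k):
        x = math.log(sbeta[s])
        lp += -x - math.log(sdlog) - 0.5 * math.log(2.0 * math.pi)
        lp += -((x - mulog) ** 2) / (2.0 * sdlog**2)
    if b_free:
        lp += -(root_b**2) / (2.0 * sdb**2) - math.log(sdb) - 0.5 * math.log(2.0 * math.pi)
        for s in range(k):
            lp += -(sb[s] ** 2) / (2.0 * sdb**2) - math.log(sdb) - 0.5 * math.log(
                2.0 * math.pi
            )
    return lp


@njit(cache=True)
def _run_mcmc(
    # tree
    parent, preorder, postorder, child_list, child_ptr, t0, t1,
    branch_nodes, cum_len,
    # data
    values, tip_var,
    # sampler settings
    n_gens, thin, burnin, gamma, mulog, sdlog, sdb, b_free,
    p_birth, p_death, p_move, p_scale,
    scale_step, b_step, max_shifts, seed, flat_lik,
    # outputs
    out_k, out_ll, out_lp,
    out_sbr, out_spos, out_sbeta, out_sb, out_rbeta, out_rb,
    prop_counts, acc_counts,
):
    np.random.seed(seed)
    n = parent.shape[0]
    total_len = cum_len[cum_len.shape[0] - 1]
    eff = np.zeros(n)
    reg_beta = np.zeros(n)
    reg_b = np.zeros(n)
    reg_ts = np.zeros(n)
    xw = np.zeros(n)
    vw = np.zeros(n)
    sbr = np.zeros(max_shifts, np.int64)
    spos = np.zeros(max_shifts)
    sbeta = np.zeros(max_shifts)
    sb = np.zeros(max_shifts)
    k = 0
    root_beta = math.exp(mulog)
    root_b = 0.0
    if flat_lik:
        cur_ll = 0.0
    else:
        cur_ll = _loglik(
            parent, preorder, postorder, child_list, child_ptr, t0, t1,
            k, sbr, spos, sbeta, sb, root_beta, root_b,
            values, tip_var, eff, reg_beta, reg_b, reg_ts, xw, vw,
        )
    s_out = 0
    for g in range(n_gens):
        u = np.random.random()
        if u < p_birth:
            move = 0
        elif u < p_birth + p_death:
            move = 1
        elif u < p_birth + p_death + p_move:
            move = 2
        elif u < p_birth + p_death + p_move + p_scale:
            move = 3
        else:
            move = 4
        prop_counts[move] += 1
        if move == 0 and k < max_shifts:
            # birth: uniform location on the tree, regime params from prior
            x = np.random.random() * total_len
            idx = np.searchsorted(cum_len, x)
            if idx >= branch_nodes.shape[0]:
                idx = branch_nodes.shape[0] - 1
            v = branch_nodes[idx]
            lo = cum_len[idx - 1] if idx > 0 else 0.0
            sbr[k] = v
            spos[k] = x - lo
            sbeta[k] = math.exp(mulog + sdlog * np.random.normal())
            sb[k] = b_step * 0.0
            if b_free:
                sb[k] = sdb * np.random.normal()
            if flat_lik:
                new_ll = 0.0
            else:
                new_ll = _loglik(
                    parent, preorder, postorder, child_list, child_ptr, t0, t1,
                    k + 1, sbr, spos, sbeta, sb, root_beta, root_b,
                    values, tip_var, eff, reg_beta, reg_b, reg_ts, xw, vw,
                )
            log_a = (new_ll - cur_ll) + math.log(gamma / (k + 1.0))
            if math.log(np.random.random() + 1e-300) < log_a:
                k += 1
                cur_ll = new_ll
                acc_counts[0] += 1
        elif move == 1 and k > 0:
            j = np.random.randint(0, k)
            obr = sbr[j]
            opos = spos[j]
            obeta = sbeta[j]
            ob = sb[j]
            sbr[j] = sbr[k - 1]
            spos[j] = spos[k - 1]
            sbeta[j] = sbeta[k - 1]
            sb[j] = sb[k - 1]
            if flat_lik:
                new_ll = 0.0
            else:
                new_ll = _loglik(
                    parent, preorder, postorder, child_list, child_ptr, t0, t1,
                    k - 1, sbr, spos, sbeta, sb, root_beta, root_b,
                    values, tip_var, eff, reg_beta, reg_b, reg_ts, xw, vw,
                )
            log_a = (new_ll - cur_ll) + math.log(k / gamma)
            if math.log(np.random.random() + 1e-300) < log_a:
                # keep deletion: restore the displaced last entry at j already
                sbr[k - 1] = obr  # park removed values beyond k (ignored)
                spos[k - 1] = opos
                sbeta[k - 1] = obeta
                sb[k - 1] = ob
                k -= 1
                cur_ll = new_ll
                acc_counts[1] += 1
            else:
                sbr[j] = obr
                spos[j] = opos
                sbeta[j] = obeta
                sb[j] = ob
        elif move == 2 and k > 0:
            j = np.random.randint(0, k)
            obr = sbr[j]
            opos = spos[j]
            x = np.random.random() * total_len
            idx = np.searchsorted(cum_len, x)
            if idx >= branch_nodes.shape[0]:
                idx = branch_nodes.shape[0] - 1
            sbr[j] = branch_nodes[idx]
            spos[j] = x - (cum_len[idx - 1] if idx > 0 else 0.0)
            if flat_lik:
                new_ll = 0.0
            else:
                new_ll = _loglik(
                    parent, preorder, postorder, child_list, child_ptr, t0, t1,
                    k, sbr, spos, sbeta, sb, root_beta, root_b,
                    values, tip_var, eff, reg_beta, reg_b, reg_ts, xw, vw,
                )
            if math.log(np.random.random() + 1e-300) < (new_ll - cur_ll):
                cur_ll = new_ll
                acc_counts[2] += 1
            else:
                sbr[j] = obr
                spos[j] = opos
        elif move == 3:
            j = np.random.randint(0, k + 1)  # 0 = root regime
            if j == 0:
                old = root_beta
            else:
                old = sbeta[j - 1]
            new = old * math.exp(scale_step * (2.0 * np.random.random() - 1.0))
            if j == 0:
                root_beta = new
            else:
                sbeta[j - 1] = new
            if flat_lik:
                new_ll = 0.0
            else:
                new_ll = _loglik(
                    parent, preorder, postorder, child_list, child_ptr, t0, t1,
                    k, sbr, spos, sbeta, sb, root_beta, root_b,
                    values, tip_var, eff, reg_beta, reg_b, reg_ts, xw, vw,
                )
            lo_old = math.log(old)
            lo_new = math.log(new)
            prior_ratio = (
                -(lo_new - mulog) ** 2 + (lo_old - mulog) ** 2
            ) / (2.0 * sdlog**2) - lo_new + lo_old
            log_a = (new_ll - cur_ll) + prior_ratio + (lo_new - lo_old)
            if math.log(np.random.random() + 1e-300) < log_a:
                cur_ll = new_ll
                acc_counts[3] += 1
            else:
                if j == 0:
                    root_beta = old
                else:
                    sbeta[j - 1] = old
        elif move == 4 and b_free:
            j = np.random.randint(0, k + 1)
            if j == 0:
                old = root_b
            else:
                old = sb[j - 1]
            new = old + b_step * np.random.normal()
            if j == 0:
                root_b = new
            else:
                sb[j - 1] = new
            if flat_lik:
                new_ll = 0.0
            else:
                new_ll = _loglik(
                    parent, preorder, postorder, child_list, child_ptr, t0, t1,
                    k, sbr, spos, sbeta, sb, root_beta, root_b,
                    values, tip_var, eff, reg_beta, reg_b, reg_ts, xw, vw,
                )
            prior_ratio = (-(new**2) + old**2) / (2.0 * sdb**2)
            log_a = (new_ll - cur_ll) + prior_ratio
            if math.log(np.random.random() + 1e-300) < log_a:
                cur_ll = new_ll
                acc_counts[4] += 1
            else:
                if j == 0:
                    root_b = old
                else:
                    sb[j - 1] = old
        # record
        if g >= burnin and (g - burnin) % thin == 0 and s_out < out_k.shape[0]:
            out_k[s_out] = k
            out_ll[s_out] = cur_ll
            out_lp[s_out] = _log_prior(
                k, sbeta, sb, root_beta, root_b,
                gamma, total_len, mulog, sdlog, sdb, b_free,
            )
            for s in range(k):
                out_sbr[s_out, s] = sbr[s]
                out_spos[s_out, s] = spos[s]
                out_sbeta[s_out, s] = sbeta[s]
                out_sb[s_out, s] = sb[s]
            out_rbeta[s_out] = root_beta
            out_rb[s_out] = root_b
            s_out += 1
    return s_out


@njit(cache=True)
def _eff_matrix(
    parent, preorder, t0, t1,
    ks, sbr, spos, sbeta, sb, rbeta, rb,
    out,
):
    """Effective branch lengths for every posterior sample (rows)."""
    n = parent.shape[0]
    reg_beta = np.zeros(n)
    reg_b = np.zeros(n)
    reg_ts = np.zeros(n)
    eff = np.zeros(n)
    for s in range(ks.shape[0]):
        _effective_lengths(
            parent, preorder, t0, t1,
            ks[s], sbr[s], spos[s], sbeta[s], sb[s], rbeta[s], rb[s],
            eff, reg_beta, reg_b, reg_ts,
        )
        for v in range(n):
            out[s, v] = eff[v]


@njit(cache=True)
def _rtt_matrix(
    parent, preorder, t0, t1, include,
    ks, sbr, spos, sbeta, sb, rbeta, rb,
    grid_abs, out,
):
    """Per-sample mean instantaneous rate across lineages alive at each
    absolute time point (NaN when no included lineage is alive)."""
    n = parent.shape[0]
    reg_beta = np.zeros(n)
    reg_b = np.zeros(n)
    reg_ts = np.zeros(n)
    eff = np.zeros(n)
    root = preorder[0]
    for s in range(ks.shape[0]):
        k = ks[s]
        _effective_lengths(
            parent, preorder, t0, t1,
            k, sbr[s], spos[s], sbeta[s], sb[s], rbeta[s], rb[s],
            eff, reg_beta, reg_b, reg_ts,
        )
        for g in range(grid_abs.shape[0]):
            a = grid_abs[g]
            tot = 0.0
            cnt = 0
            for v in range(n):
                if v == root or not include[v]:
                    continue
                if t0[v] < a and a <= t1[v]:
                    p = parent[v]
                    beta = reg_beta[p]
                    b = reg_b[p]
                    ts = reg_ts[p]
                    best = -1.0
                    for sh in range(k):
                        if sbr[s, sh] == v:
                            st = t0[v] + spos[s, sh]
                            if st <= a and spos[s, sh] > best:
                                best = spos[s, sh]
                                beta = sbeta[s, sh]
                                b = sb[s, sh]
                                ts = st
                    tot += beta * math.exp(b * (a - ts))
                    cnt += 1
            if cnt > 0:
                out[s, g] = tot / cnt
            else:
                out[s, g] = np.nan
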