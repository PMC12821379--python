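"""Numba kernels for growing multivariate regression trees.

The splitting criterion is the node-standardized multivariate rule: responses
are rescaled inside each node to mean 0 / mean-square 1, and a split is scored
by summing, over the scored responses, G_j = (sum_L Y*)^2/n_L + (sum_R Y*)^2/n_R.
Because node standardization makes each Y* column sum to zero over the node,
sum_R = -sum_L, so G_j = c_j^2 (1/n_L + 1/n_R) with c_j the running left sum —
this lets the scan over sorted predictor values maintain the total score
incrementally in O(q) per sample.
"""

import numpy as np
from numba import njit

# node encoding: feature[v] >= 0 -> internal, goes left when x <= threshold[v];
# feature[v] == -1 -> leaf.


@njit(cache=True)
def _partial_shuffle(arr, k):
    # Fisher-Yates for the first k entries of arr (in place).
    n = arr.shape[0]
    for i in range(k):
        j = i + np.random.randint(0, n - i)
        tmp = arr[i]
        arr[i] = arr[j]
        arr[j] = tmp


@njit(cache=True, fastmath=True)
def grow_tree(X, Y, samp, mtry, nodesize, max_depth, n_resp, nsplit, seed):
    """Grow one tree on the bootstrap sample `samp` (sample indices, with
    repeats).  Returns flat node arrays; `max_depth < 0` means unlimited,
    `n_resp` is the number of responses scored per split (<= q), `nsplit == 0`
    means exhaustive thresholds.
    """
    np.random.seed(seed)
    n = samp.shape[0]
    p = X.shape[1]
    q = Y.shape[1]
    max_nodes = 2 * n + 1

    feature = np.full(max_nodes, -1, np.int64)
    threshold = np.zeros(max_nodes)
    left = np.full(max_nodes, -1, np.int64)
    right = np.full(max_nodes, -1, np.int64)
    depth = np.zeros(max_nodes, np.int64)
    msrv = np.full(max_nodes, -1, np.int64)
    score = np.zeros(max_nodes)
    nl_arr = np.zeros(max_nodes, np.int64)
    nr_arr = np.zeros(max_nodes, np.int64)
    gains = np.zeros((max_nodes, q))

    pos = samp.copy()

    # explicit stack of (start, end, depth, node_id)
    stack = np.empty((max_nodes, 4), np.int64)
    top = 0
    stack[0, 0] = 0
    stack[0, 1] = n
    stack[0, 2] = 0
    stack[0, 3] = 0
    top = 1
    n_nodes = 1

    feat_pool = np.arange(p)
    resp_pool = np.arange(q)

    xv = np.empty(n)
    mu = np.empty(q)
    sd = np.empty(q)
    tmp = np.empty(n, np.int64)

    while top > 0:
        top -= 1
        s = stack[top, 0]
        e = stack[top, 1]
        d = stack[top, 2]
        node = stack[top, 3]
        m = e - s
        depth[node] = d

        if m < 2 * nodesize or (max_depth >= 0 and d >= max_depth):
            continue  # leaf

        # responses scored at this split
        if n_resp < q:
            _partial_shuffle(resp_pool, n_resp)
            ridx = np.sort(resp_pool[:n_resp])
        else:
            ridx = resp_pool
        qs = ridx.shape[0]

        # node standardization: mean 0, mean-square 1 per scored response;
        # zero-variance columns contribute 0 to every score.
        any_var = False
        for jj in range(qs):
            j = ridx[jj]
            acc = 0.0
            acc2 = 0.0
            for i in range(s, e):
                y = Y[pos[i], j]
                acc += y
                acc2 += y * y
            mn = acc / m
            var = acc2 / m - mn * mn
            mu[jj] = mn
            if var > 1e-24:
                sd[jj] = np.sqrt(var)
                any_var = True
            else:
                sd[jj] = 0.0
        if not any_var:
            continue  # all scored responses constant: leaf

        # standardized responses in single precision for the scan; the chosen
        # split's per-response scores are recomputed in double precision below
        Z = np.zeros((m, qs), np.float32)
        for i in range(m):
            row = pos[s + i]
            for jj in range(qs):
                if sd[jj] > 0.0:
                    Z[i, jj] = np.float32((Y[row, ridx[jj]] - mu[jj]) / sd[jj])

        _partial_shuffle(feat_pool, mtry)

        best_g = 0.0
        best_f = -1
        best_thr = 0.0
        c = np.zeros(qs, np.float32)

        for fk in range(mtry):
            f = feat_pool[fk]
            for i in range(m):
                xv[i] = X[pos[s + i], f]
            order = np.argsort(xv[:m])
            if xv[order[0]] == xv[order[m - 1]]:
                continue

            # optional random subsampling of candidate thresholds
            use_all = True
            allow = tmp  # reuse buffer as 0/1 mask over positions
            if nsplit > 0:
                nb = 0
                for i in range(m - 1):
                    if xv[order[i]] < xv[order[i + 1]]:
                        nb += 1
                if nb > nsplit:
                    use_all = False
                    for i in range(m - 1):
                        allow[i] = 0
                    picked = 0
                    while picked < nsplit:
                        r = np.random.randint(0, m - 1)
                        if xv[order[r]] < xv[order[r + 1]] and allow[r] == 0:
                            allow[r] = 1
                            picked += 1

            for jj in range(qs):
                c[jj] = np.float32(0.0)
            ssum = np.float32(0.0)
            two = np.float32(2.0)
            for i in range(m - 1):
                row = order[i]
                for jj in range(qs):
                    y = Z[row, jj]
                    ssum += y * (two * c[jj] + y)
                    c[jj] += y
                if xv[order[i]] < xv[order[i + 1]]:
                    if use_all or allow[i] == 1:
                        nL = i + 1
                        g = float(ssum) * (1.0 / nL + 1.0 / (m - nL))
                        thr = 0.5 * (xv[order[i]] + xv[order[i + 1]])
                        # scores within relative 1e-4 are treated as tied
                        # (the scan accumulates in single precision); ties
                        # break to lower predictor index, then lower threshold
                        tol = 1e-4 * best_g
                        if best_f < 0:
                            if g > 0.0:
                                best_g = g
                                best_f = f
                                best_thr = thr
                        elif g > best_g + tol:
                            best_g = g
                            best_f = f
                            best_thr = thr
                        elif g >= best_g - tol and (
                            f < best_f or (f == best_f and thr < best_thr)
                        ):
                            if g > best_g:
                                best_g = g
                            best_f = f
                            best_thr = thr

        if best_f < 0 or best_g <= 0.0:
            continue  # no score-improving split: leaf

        # per-response scores G_j for the chosen split, recomputed in double
        # precision over ALL responses: the split is searched on the scored
        # subset, but the maximal splitting response variable is the argmax of
        # G_j over the full response set
        for i in range(m):
            xv[i] = X[pos[s + i], best_f]
        mu_all = np.zeros(q)
        sd_all = np.zeros(q)
        for j in range(q):
            acc = 0.0
            acc2 = 0.0
            for i in range(s, e):
                y = Y[pos[i], j]
                acc += y
                acc2 += y * y
            mn = acc / m
            var = acc2 / m - mn * mn
            mu_all[j] = mn
            if var > 1e-24:
                sd_all[j] = np.sqrt(var)
        nL = 0
        cd = np.zeros(q)
        for i in range(m):
            if xv[i] <= best_thr:
                nL += 1
                row = pos[s + i]
                for j in range(q):
                    if sd_all[j] > 0.0:
                        cd[j] += (Y[row, j] - mu_all[j]) / sd_all[j]
        nR = m - nL
        tot = 0.0
        best_j = -1
        best_gj = -1.0
        for j in range(q):
            gj = cd[j] * cd[j] * (1.0 / nL + 1.0 / nR)
            gains[node, j] = gj
            tot += gj
            if gj > best_gj:
                best_gj = gj
                best_j = j

        feature[node] = best_f
        threshold[node] = best_thr
        score[node] = tot
        msrv[node] = best_j
        nl_arr[node] = nL
        nr_arr[node] = nR

        # partition pos[s:e] into (x <= thr | x > thr), stable
        k = 0
        for i in range(m):
            if xv[i] <= best_thr:
                tmp[k] = pos[s + i]
                k += 1
        for i in range(m):
            if xv[i] > best_thr:
                tmp[k] = pos[s + i]
                k += 1
        for i in range(m):
            pos[s + i] = tmp[i]

        lid = n_nodes
        rid = n_nodes + 1
        n_nodes += 2
        left[node] = lid
        right[node] = rid
        stack[top, 0] = s
        stack[top, 1] = s + nL
        stack[top, 2] = d + 1
        stack[top, 3] = lid
        top += 1
        stack[top, 0] = s + nL
        stack[top, 1] = e
        stack[top, 2] = d + 1
        stack[top, 3] = rid
        top += 1

    return (
        feature[:n_nodes],
        threshold[:n_nodes],
        left[:n_nodes],
        right[:n_nodes],
        depth[:n_nodes],
        msrv[:n_nodes],
        score[:n_nodes],
        nl_arr[:n_nodes],
        nr_arr[:n_nodes],
        gains[:n_nodes],
    )


@njit(cache=True)
def apply_tree(feature, threshold, left, right, X):
    """Terminal-node id for every row of X."""
    n = X.shape[0]
    out = np.empty(n, np.int64)
    for i in range(n):
        node = 0
        while feature[node] >= 0:
            if X[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = node
    return out


@njit(cache=True)
def leaf_inbag_means(leaf_id, inbag_counts, V, n_nodes):
    """In-bag (multiplicity-weighted) mean of each column of V per leaf."""
    n, d = V.shape
    sums = np.zeros((n_nodes, d))
    cnt = np.zeros(n_nodes)
    for i in range(n):
        w = inbag_counts[i]
        if w > 0:
            lf = leaf_id[i]
            cnt[lf] += w
            for j in range(d):
                sums[lf, j] += w * V[i, j]
    for lf in range(n_nodes):
        if cnt[lf] > 0:
            for j in range(d):
                sums[lf, j] /= cnt[lf]
    return sums


@njit(cache=True)
def accumulate_oob(leaf_id, inbag_counts, leaf_means, preds, counts):
    """Add this tree's leaf-mean prediction for its out-of-bag samples."""
    n = leaf_id.shape[0]
    d = leaf_means.shape[1]
    for i in range(n):
        if inbag_counts[i] == 0:
            lf = leaf_id[i]
            counts[i] += 1
            for j in range(d):
                preds[i, j] += leaf_means[lf, j]
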