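"""Numba kernels for CART growing, traversal and OOB permutation importance.

Genotypes are ordinal int8 predictors in {0,1,2} with exactly two candidate
cutpoints per variable (left = {0} vs {1,2} encoded as cut 0, and
left = {0,1} vs {2} encoded as cut 1).  Trees are stored as flat parallel
arrays (feature == -1 marks a leaf).  All randomness inside the kernels goes
through numba's per-process legacy RNG, re-seeded explicitly per call, so a
(seed, inputs) pair reproduces bit-identical trees.
"""

import numpy as np
from numba import njit

#: absolute tolerance for comparing Gini gains when breaking split ties
_GAIN_TOL = 1e-12


@njit(cache=True)
def grow_tree_kernel(X, y, samples, mtry, min_node_size, seed):
    """Grow one unpruned classification tree on the in-bag ``samples``.

    ``samples`` is the bootstrap index multiset (length n); it is partitioned
    in place.  Returns flat node arrays plus the per-node weighted impurity
    decrease used for Gini importance.
    """
    p = X.shape[1]
    n_inbag = samples.size
    max_nodes = 2 * n_inbag + 1
    feature = np.full(max_nodes, -1, np.int32)
    cut = np.zeros(max_nodes, np.int8)
    left = np.full(max_nodes, -1, np.int32)
    right = np.full(max_nodes, -1, np.int32)
    pred = np.zeros(max_nodes, np.int8)
    gain = np.zeros(max_nodes, np.float64)

    np.random.seed(seed)
    pool = np.arange(p)
    cnt = np.zeros((3, 2), np.int64)

    stack = np.empty((max_nodes, 3), np.int64)
    stack[0, 0] = 0
    stack[0, 1] = 0
    stack[0, 2] = n_inbag
    top = 1
    n_nodes = 1
    m = mtry if mtry < p else p

    while top > 0:
        top -= 1
        node = stack[top, 0]
        start = stack[top, 1]
        end = stack[top, 2]
        size = end - start
        c1 = 0
        for s in range(start, end):
            c1 += y[samples[s]]
        c0 = size - c1
        pred[node] = 1 if c1 > c0 else 0
        if c0 == 0 or c1 == 0 or size <= min_node_size:
            continue
        i_parent = 1.0 - (c0 / size) ** 2 - (c1 / size) ** 2

        best_d = 0.0
        best_v = -1
        best_c = -1
        for i in range(m):
            j = i + np.random.randint(p - i)
            tmp = pool[i]
            pool[i] = pool[j]
            pool[j] = tmp
            v = pool[i]
            cnt[:, :] = 0
            for s in range(start, end):
                cnt[X[samples[s], v], y[samples[s]]] += 1
            for cth in range(2):
                if cth == 0:
                    l0 = cnt[0, 0]
                    l1 = cnt[0, 1]
                else:
                    l0 = cnt[0, 0] + cnt[1, 0]
                    l1 = cnt[0, 1] + cnt[1, 1]
                nL = l0 + l1
                nR = size - nL
                if nL == 0 or nR == 0:
                    continue
                r0 = c0 - l0
                r1 = c1 - l1
                iL = 1.0 - (l0 / nL) ** 2 - (l1 / nL) ** 2
                iR = 1.0 - (r0 / nR) ** 2 - (r1 / nR) ** 2
                d = i_parent - (nL / size) * iL - (nR / size) * iR
                if d <= _GAIN_TOL:
                    continue
                if best_v == -1 or d > best_d + _GAIN_TOL:
                    best_d = d
                    best_v = v
                    best_c = cth
                elif d >= best_d - _GAIN_TOL and (
                    v < best_v or (v == best_v and cth < best_c)
                ):
                    if d > best_d:
                        best_d = d
                    best_v = v
                    best_c = cth
        if best_v == -1:
            continue

        feature[node] = best_v
        cut[node] = best_c
        gain[node] = (size / n_inbag) * best_d
        lo = start
        hi = end - 1
        while lo <= hi:
            if X[samples[lo], best_v] <= best_c:
                lo += 1
            else:
                tmp = samples[lo]
                samples[lo] = samples[hi]
                samples[hi] = tmp
                hi -= 1
        l_id = n_nodes
        r_id = n_nodes + 1
        n_nodes += 2
        left[node] = l_id
        right[node] = r_id
        stack[top, 0] = r_id
        stack[top, 1] = lo
        stack[top, 2] = end
        top += 1
        stack[top, 0] = l_id
        stack[top, 1] = start
        stack[top, 2] = lo
        top += 1

    return (
        feature[:n_nodes],
        cut[:n_nodes],
        left[:n_nodes],
        right[:n_nodes],
        pred[:n_nodes],
        gain[:n_nodes],
    )


@njit(cache=True)
def predict_tree_kernel(feature, cut, left, right, pred, X, idx):
    out = np.empty(idx.size, np.int8)
    for ii in range(idx.size):
        i = idx[ii]
        node = 0
        while feature[node] >= 0:
            if X[i, feature[node]] <= cut[node]:
                node = left[node]
            else:
                node = right[node]
        out[ii] = pred[node]
    return out


@njit(cache=True)
def perm_importance_tree_kernel(
    feature, cut, left, right, pred, X, y, oob_idx, used_vars, seed, sum_d, sumsq_d, used_count
):
    """Accumulate per-variable OOB accuracy decreases for one tree.

    For each variable used in the tree, its values are permuted once among the
    tree's OOB individuals and the drop in OOB accuracy is added to the
    per-variable running sums (``sum_d``, ``sumsq_d``, ``used_count``).
    """
    n_oob = oob_idx.size
    if n_oob == 0:
        for vv in range(used_vars.size):
            used_count[used_vars[vv]] += 1
        return
    np.random.seed(seed)
    correct = 0
    for ii in range(n_oob):
        i = oob_idx[ii]
        node = 0
        while feature[node] >= 0:
            if X[i, feature[node]] <= cut[node]:
                node = left[node]
            else:
                node = right[node]
        if pred[node] == y[i]:
            correct += 1
    acc = correct / n_oob

    order = np.empty(n_oob, np.int64)
    permuted = np.empty(n_oob, np.int8)
    for vv in range(used_vars.size):
        v = used_vars[vv]
        for ii in range(n_oob):
            order[ii] = ii
        for ii in range(n_oob - 1, 0, -1):
            j = np.random.randint(ii + 1)
            tmp = order[ii]
            order[ii] = order[j]
            order[j] = tmp
        for ii in range(n_oob):
            permuted[ii] = X[oob_idx[order[ii]], v]
        correct = 0
        for ii in range(n_oob):
            i = oob_idx[ii]
            node = 0
            while feature[node] >= 0:
                f = feature[node]
                if f == v:
                    val = permuted[ii]
                else:
                    val = X[i, f]
                if val <= cut[node]:
                    node = left[node]
                else:
                    node = right[node]
            if pred[node] == y[i]:
                correct += 1
        d = acc - correct / n_oob
        sum_d[v] += d
        sumsq_d[v] += d * d
        used_count[v] += 1
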