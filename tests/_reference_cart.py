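"""Independent reference CART used as an oracle.

Deliberately written with plain scalar loops and its own arithmetic so it
shares no code path with the package implementation.  Same contract: splits
at midpoints of consecutive distinct sorted values, count-weighted Gini
decrease, tie rule = lowest feature index then smallest threshold, routing
``< threshold`` left / ``>= threshold`` right.
"""

from __future__ import annotations


def ref_gini(n_pos: int, n_neg: int) -> float:
    total = n_pos + n_neg
    p = n_pos / total
    q = n_neg / total
    return 1.0 - p * p - q * q


def ref_best_split(rows, labels, min_leaf=1):
    """Exhaustive scan over every (feature, midpoint) candidate.

    Returns (feature_index, threshold, decrease) or None.
    """
    n = len(labels)
    if n < 2:
        return None
    n_pos = sum(labels)
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    parent = n * ref_gini(n_pos, n_neg)
    p = len(rows[0])

    best = None
    for fi in range(p):
        pairs = sorted((rows[i][fi], labels[i]) for i in range(n))
        left_pos = 0
        left_n = 0
        for i in range(n - 1):
            left_pos += pairs[i][1]
            left_n += 1
            if pairs[i][0] == pairs[i + 1][0]:
                continue
            right_n = n - left_n
            if left_n < min_leaf or right_n < min_leaf:
                continue
            right_pos = n_pos - left_pos
            child = left_n * ref_gini(left_pos, left_n - left_pos) + right_n * ref_gini(
                right_pos, right_n - right_pos
            )
            decrease = parent - child
            if decrease <= 0:
                continue
            threshold = 0.5 * (pairs[i][0] + pairs[i + 1][0])
            if best is None or decrease > best[2]:
                best = (fi, threshold, decrease)
    return best


def ref_grow(rows, labels, max_depth=None, min_split=2, min_leaf=1,
             min_rel_decrease=0.0):
    """Recursive reference tree; nodes are dicts mirroring the package's
    node structure: counts, feature index, threshold, children."""
    n_root = len(labels)
    root_imp = n_root * ref_gini(sum(labels), n_root - sum(labels))

    def build(rows, labels, depth):
        n = len(labels)
        n_pos = sum(labels)
        node = {"counts": (n_pos, n - n_pos)}
        if n_pos == 0 or n_pos == n or n < min_split:
            return node
        if max_depth is not None and depth >= max_depth:
            return node
        found = ref_best_split(rows, labels, min_leaf)
        if found is None:
            return node
        fi, thr, dec = found
        if root_imp > 0 and dec / root_imp < min_rel_decrease:
            return node
        node["feature"] = fi
        node["threshold"] = thr
        left_rows, left_y, right_rows, right_y = [], [], [], []
        for row, lab in zip(rows, labels):
            if row[fi] < thr:
                left_rows.append(row)
                left_y.append(lab)
            else:
                right_rows.append(row)
                right_y.append(lab)
        node["left"] = build(left_rows, left_y, depth + 1)
        node["right"] = build(right_rows, right_y, depth + 1)
        return node

    return build(rows, labels, 0)


def same_tree(ref_node, pkg_node, rel_tol=0.0):
    """Structural equality between a reference dict-tree and a package
    TreeNode (exact feature/threshold/counts match)."""
    if tuple(ref_node["counts"]) != tuple(pkg_node.class_counts):
        return False
    ref_leaf = "feature" not in ref_node
    if ref_leaf != pkg_node.is_leaf:
        return False
    if ref_leaf:
        return True
    if ref_node["feature"] != pkg_node.feature_index:
        return False
    if ref_node["threshold"] != pkg_node.threshold:
        return False
    return same_tree(ref_node["left"], pkg_node.left) and same_tree(
        ref_node["right"], pkg_node.right
    )
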