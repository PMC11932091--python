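"""Independent brute-force oracles used to validate the implementation.

Each oracle is written as a direct, loop-based transcription of the relevant
definition and never calls into the package's computational paths.
"""

import numpy as np
from Bio.Align import substitution_matrices


def pairwise_cosine_bruteforce(profiles):
    """Double-loop cosine similarity matrix; zero-norm rows give 0."""
    P = np.asarray(profiles, dtype=float)
    n = P.shape[0]
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            ni = np.sqrt((P[i] ** 2).sum())
            nj = np.sqrt((P[j] ** 2).sum())
            if ni > 0 and nj > 0:
                S[i, j] = float(P[i] @ P[j]) / (ni * nj)
    return S


def sw_local_identity(s1, s2, gap_open=10.0, gap_extend=0.5, matrix_name="BLOSUM62"):
    """Quadratic affine-gap Smith-Waterman (Gotoh) with backpointer traceback.

    Returns matches / alignment-length of the optimal local alignment, 0 if
    no positive-scoring alignment exists.
    """
    sub = substitution_matrices.load(matrix_name)
    n, m = len(s1), len(s2)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))       # best ending in an aligned column
    E = np.full((n + 1, m + 1), NEG)   # gap in s2 (moving down s1)
    F = np.full((n + 1, m + 1), NEG)   # gap in s1 (moving along s2)
    ptr_h = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0=start, 1=H, 2=E, 3=F
    ptr_e = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1=H, 2=E
    ptr_f = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1=H, 3=F
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            from_h = H[i - 1, j] - gap_open
            from_e = E[i - 1, j] - gap_extend
            E[i, j], ptr_e[i, j] = (from_h, 1) if from_h >= from_e else (from_e, 2)
            from_h = H[i, j - 1] - gap_open
            from_f = F[i, j - 1] - gap_extend
            F[i, j], ptr_f[i, j] = (from_h, 1) if from_h >= from_f else (from_f, 3)
            s = sub[s1[i - 1], s2[j - 1]]
            options = [(H[i - 1, j - 1], 1), (E[i - 1, j - 1], 2), (F[i - 1, j - 1], 3)]
            prev, code = max(options, key=lambda t: t[0])
            diag = prev + s
            if diag <= 0 or prev == NEG:
                diag, code = (s, 0) if s > 0 else (0.0, 0)
            H[i, j], ptr_h[i, j] = diag, code
            if H[i, j] > best:
                best, bi, bj = H[i, j], i, j
    if best <= 0:
        return 0.0
    i, j, state = bi, bj, 1
    matches, length = 0, 0
    while i > 0 and j > 0 and not (state == 1 and H[i, j] <= 0):
        if state == 1:
            length += 1
            if s1[i - 1] == s2[j - 1]:
                matches += 1
            nxt = ptr_h[i, j]
            i, j = i - 1, j - 1
            if nxt == 0:
                break
            state = nxt
        elif state == 2:
            length += 1
            state = ptr_e[i, j]
            i -= 1
        else:
            length += 1
            state = ptr_f[i, j]
            j -= 1
    return matches / length if length else 0.0


def gcn_forward_dense(A, X, W1, b1, W2, b2):
    """Two-layer graph convolution with explicit normalization loops."""
    n = A.shape[0]
    A_hat = np.asarray(A, dtype=float) + np.eye(n)
    d = A_hat.sum(axis=1)
    norm = np.zeros_like(A_hat)
    for i in range(n):
        for j in range(n):
            norm[i, j] = A_hat[i, j] / np.sqrt(d[i] * d[j])
    H1 = np.maximum(norm @ X @ W1 + b1, 0.0)
    return norm @ H1 @ W2 + b2


def dmpnn_forward_enumerate(graph, W_in, b_in, W_msg, W_atom, b_atom, n_layers=1):
    """Directed message passing with explicit incoming-edge enumeration."""
    X = graph.atom_features
    nE = graph.n_edges
    relu = lambda v: np.maximum(v, 0.0)
    h0 = np.zeros((nE, W_in.shape[1]))
    for e in range(nE):
        h0[e] = relu(np.concatenate([X[graph.edge_src[e]], graph.bond_features[e]]) @ W_in + b_in)
    h = h0.copy()
    for _ in range(n_layers):
        h_new = np.zeros_like(h)
        for e in range(nE):
            v = graph.edge_src[e]
            m = np.zeros(W_in.shape[1])
            for k in range(nE):
                if graph.edge_dst[k] == v and k != graph.rev_index[e]:
                    m += h[k]
            h_new[e] = relu(h0[e] + m @ W_msg)
        h = h_new
    atoms = np.zeros((graph.n_atoms, W_in.shape[1]))
    for v in range(graph.n_atoms):
        m = np.zeros(W_in.shape[1])
        for k in range(nE):
            if graph.edge_dst[k] == v:
                m += h[k]
        atoms[v] = relu(np.concatenate([X[v], m]) @ W_atom + b_atom)
    return atoms.mean(axis=0)


def conv1d_sliding(x, w, b):
    """Same-padded stride-1 convolution via explicit window dot products.

    x: (L, Cin), w: (K, Cin, Cout), b: (Cout,) -> (L, Cout).
    """
    L, Cin = x.shape
    K, _, Cout = w.shape
    pad = K // 2
    xp = np.zeros((L + 2 * pad, Cin))
    xp[pad:pad + L] = x
    out = np.zeros((L, Cout))
    for t in range(L):
        for c in range(Cout):
            acc = b[c]
            for k in range(K):
                acc += float(xp[t + k] @ w[k, :, c])
            out[t, c] = acc
    return out


def auc_pair_count(labels, scores):
    """AUC by enumerating every positive-negative pair (ties count 1/2)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
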