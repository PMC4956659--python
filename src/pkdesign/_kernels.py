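"""Numerical kernels (numba-jitted) for ensemble computation.

Two exact engines live here:

* an iterative depth-first enumerator over all two-page secondary
  structures of a sequence, pruning non-bipartite crossing graphs
  incrementally with a parity union-find, and accumulating the partition
  function, pair-probability matrices and the MFE structure in one pass;

* the dynamic programs for the pseudoknot-free (nested) ensemble:
  inside/outside partition functions with per-nucleotide rescaling so
  the arithmetic never overflows on long sequences, and the
  minimum-energy matrix.

Everything here is 0-based; the public modules convert to 1-based
coordinates at the boundary.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MIN_LOOP_SPAN = 3


@njit(cache=True)
def _find(parent, par, x):
    """Root and parity of pair *x* in the parity union-find (no compression)."""
    p = 0
    while parent[x] != x:
        p ^= par[x]
        x = parent[x]
    return x, p


@njit(cache=True)
def _dotbracket_codes(n, partner, page2, out):
    """Character codes for lexicographic MFE tie-breaking.

    Uses the ASCII codes of '(' 40, ')' 41, '.' 46, '[' 91, ']' 93 so that
    comparing code arrays equals comparing dot-bracket strings.
    """
    for a in range(n):
        b = partner[a]
        if b < 0:
            out[a] = 46
        elif b > a:
            out[a] = 91 if page2[a] else 40
        else:
            out[a] = 93 if page2[a] else 41


@njit(cache=True)
def _build_candidates(n, emat):
    """CSR candidate partner lists per opening position."""
    counts = np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        for j in range(i + MIN_LOOP_SPAN, n):
            if not np.isinf(emat[i, j]):
                counts[i + 1] += 1
    cstart = np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        cstart[i + 1] = cstart[i] + counts[i + 1]
    cj = np.zeros(cstart[n], dtype=np.int64)
    ce = np.zeros(cstart[n], dtype=np.float64)
    k = 0
    for i in range(n):
        for j in range(i + MIN_LOOP_SPAN, n):
            if not np.isinf(emat[i, j]):
                cj[k] = j
                ce[k] = emat[i, j]
                k += 1
    return cstart, cj, ce


@njit(cache=True)
def enumerate_two_page(n, emat, kbt, pk_pen, pk_init, eshift, pk_allowed):
    """Enumerate every admissible structure of one sequence in one DFS pass.

    Parameters
    ----------
    emat : (n, n) float64
        ``emat[i, j]`` is the pair energy of (i, j) for j >= i+3, +inf if
        the bases cannot pair.  Only the upper triangle is read.
    kbt : float
        Thermal energy k_B * T in kcal/mol.
    pk_pen : float
        Energy penalty added per page-2 (pseudoknot) pair.
    pk_init : float
        One-time initiation penalty per pseudoknot, i.e. per connected
        component of the crossing graph containing at least two pairs.
    eshift : float
        A lower bound on any structure energy; Boltzmann weights are
        computed as exp((eshift - E)/kbt) <= 1 so the sum cannot overflow.
    pk_allowed : bool
        If False, any crossing pair is pruned (nested-only ensemble).

    Returns
    -------
    (q_shifted, count, P, P1, P2, mfe_partner, mfe_page2, mfe_energy)
        ``P`` is n x (n+1) with the unpaired column last; ``P1``/``P2``
        are the nested / non-nested page splits (P1 + P2 equals P on the
        first n columns).  All three are normalized by the partition
        function.  ``q_shifted * exp(-eshift/kbt)`` is the true Q.

    Page assignment per structure is canonical: within each connected
    component of the crossing graph the 5'-most pair takes page 1 and
    the 2-coloring is propagated, exactly as ``structures.two_page_split``
    does.  Pairs are created in 5'-order during the DFS, so the smallest
    pair id in a union-find component is its 5'-most pair.

    Costing: the pseudoknot energy terms are maintained incrementally
    (per-root parity counts in the union-find), total pair probabilities
    are accumulated per DFS edge as subtree partition-function sums, the
    unpaired column is the row-sum complement, and only the page-2 mass
    needs a per-leaf scan (and only on leaves that contain crossings).
    """
    maxp = n // 2 + 1

    partner = np.full(n, -1, dtype=np.int64)
    pr_i = np.zeros(maxp, dtype=np.int64)
    pr_j = np.zeros(maxp, dtype=np.int64)
    top = 0
    esum = 0.0        # sum of pair energies on the current path
    n2_total = 0      # current count of page-2 pairs
    npk_total = 0     # current count of pseudoknots (nontrivial components)

    # parity union-find over pair ids (== stack depth at creation);
    # per-root bookkeeping: 5'-most member and parity counts
    parent = np.zeros(maxp, dtype=np.int64)
    par = np.zeros(maxp, dtype=np.int64)
    minid = np.zeros(maxp, dtype=np.int64)   # smallest pair id in component
    minpar = np.zeros(maxp, dtype=np.int64)  # its parity relative to the root
    cnt0 = np.zeros(maxp, dtype=np.int64)    # members with parity 0 (vs root)
    cnt1 = np.zeros(maxp, dtype=np.int64)    # members with parity 1

    # undo log for unions: child root linked under absorbing root
    cap = maxp + 1
    ulog_child = np.zeros(cap, dtype=np.int64)
    ulog_root = np.zeros(cap, dtype=np.int64)
    ulog_minid = np.zeros(cap, dtype=np.int64)
    ulog_minpar = np.zeros(cap, dtype=np.int64)
    ulog_cnt0 = np.zeros(cap, dtype=np.int64)
    ulog_cnt1 = np.zeros(cap, dtype=np.int64)
    ulog_n2 = np.zeros(cap, dtype=np.int64)
    ulog_npk = np.zeros(cap, dtype=np.int64)
    utop = 0
    ustart = np.zeros(n + 1, dtype=np.int64)  # union-log watermark per DFS level

    # per-level DFS bookkeeping: -3 forced skip, -2 fresh, -1 unpaired,
    # >=0 index into the CSR candidate arrays
    lv_choice = np.full(n + 1, -2, dtype=np.int64)
    cstart, cj, ce = _build_candidates(n, emat)
    qmark = np.zeros(n + 1, dtype=np.float64)  # Q watermark at pair push

    # accumulators
    q = 0.0
    count = 0
    P = np.zeros((n, n + 1), dtype=np.float64)
    P2 = np.zeros((n, n), dtype=np.float64)
    mfe_energy = np.inf
    mfe_partner = np.full(n, -1, dtype=np.int64)
    mfe_page2 = np.zeros(n, dtype=np.int64)
    cur_page2 = np.zeros(n, dtype=np.int64)
    cur_codes = np.zeros(n, dtype=np.int64)
    best_codes = np.zeros(n, dtype=np.int64)

    pos = 0
    going_down = True
    while True:
        if going_down:
            if pos == n:
                # ---- leaf: one complete structure ----
                etot = esum + pk_pen * n2_total + pk_init * npk_total
                w = np.exp((eshift - etot) / kbt)
                q += w
                count += 1
                if n2_total > 0:
                    for d in range(top):
                        r, p = _find(parent, par, d)
                        if p != minpar[r]:
                            P2[pr_i[d], pr_j[d]] += w
                if etot <= mfe_energy + 1e-12:
                    # candidate new MFE (or a tie): resolve pages explicitly
                    for d in range(top):
                        r, p = _find(parent, par, d)
                        flag = 1 if p != minpar[r] else 0
                        cur_page2[pr_i[d]] = flag
                        cur_page2[pr_j[d]] = flag
                    take = etot < mfe_energy - 1e-12
                    if not take:
                        _dotbracket_codes(n, partner, cur_page2, cur_codes)
                        for a in range(n):
                            if cur_codes[a] < best_codes[a]:
                                take = True
                                break
                            if cur_codes[a] > best_codes[a]:
                                break
                    if take:
                        mfe_energy = etot
                        for a in range(n):
                            mfe_partner[a] = partner[a]
                            if partner[a] >= 0:
                                mfe_page2[a] = cur_page2[a]
                            else:
                                mfe_page2[a] = 0
                        _dotbracket_codes(n, partner, mfe_page2, best_codes)
                going_down = False
                pos -= 1
                continue
            if partner[pos] >= 0:
                lv_choice[pos] = -3
                pos += 1
                continue
            lv_choice[pos] = -1  # try unpaired first
            pos += 1
            continue

        # ---- coming back up to pos: advance its choice ----
        if pos < 0:
            break
        c = lv_choice[pos]
        if c == -3:
            pos -= 1
            continue
        if c >= 0:
            # pop the pair (pos, cj[c]): credit its subtree mass to P
            jc = cj[c]
            sub = q - qmark[pos]
            P[pos, jc] += sub
            P[jc, pos] += sub
            top -= 1
            esum -= ce[c]
            partner[pos] = -1
            partner[jc] = -1
            while utop > ustart[pos]:
                utop -= 1
                ch = ulog_child[utop]
                rt = ulog_root[utop]
                parent[ch] = ch
                par[ch] = 0
                minid[rt] = ulog_minid[utop]
                minpar[rt] = ulog_minpar[utop]
                cnt0[rt] = ulog_cnt0[utop]
                cnt1[rt] = ulog_cnt1[utop]
                n2_total = ulog_n2[utop]
                npk_total = ulog_npk[utop]
        # next candidate partner
        kstart = cstart[pos] if c == -1 else c + 1
        advanced = False
        for k in range(kstart, cstart[pos + 1]):
            j = cj[k]
            if partner[j] >= 0:
                continue
            # try to push pair (pos, j) with id = top
            d = top
            parent[d] = d
            par[d] = 0
            minid[d] = d
            minpar[d] = 0
            cnt0[d] = 1
            cnt1[d] = 0
            ustart[pos] = utop
            ok = True
            for e in range(top):
                if pos < pr_j[e] < j:  # existing pair (pr_i[e] < pos) crosses (pos, j)
                    if not pk_allowed:
                        ok = False
                        break
                    rd, pd = _find(parent, par, d)
                    re, pe = _find(parent, par, e)
                    if rd == re:
                        if pd == pe:
                            ok = False
                            break
                    else:
                        # link rd under re with parity making d and e differ
                        ulog_child[utop] = rd
                        ulog_root[utop] = re
                        ulog_minid[utop] = minid[re]
                        ulog_minpar[utop] = minpar[re]
                        ulog_cnt0[utop] = cnt0[re]
                        ulog_cnt1[utop] = cnt1[re]
                        ulog_n2[utop] = n2_total
                        ulog_npk[utop] = npk_total
                        utop += 1
                        # retire both components' pseudoknot contributions
                        size_re = cnt0[re] + cnt1[re]
                        size_rd = cnt0[rd] + cnt1[rd]
                        n2_re = cnt1[re] if minpar[re] == 0 else cnt0[re]
                        n2_rd = cnt1[rd] if minpar[rd] == 0 else cnt0[rd]
                        n2_total -= n2_re + n2_rd
                        if size_re >= 2:
                            npk_total -= 1
                        if size_rd >= 2:
                            npk_total -= 1
                        lnk = pd ^ pe ^ 1
                        parent[rd] = re
                        par[rd] = lnk
                        if lnk == 0:
                            cnt0[re] += cnt0[rd]
                            cnt1[re] += cnt1[rd]
                        else:
                            cnt0[re] += cnt1[rd]
                            cnt1[re] += cnt0[rd]
                        if minid[rd] < minid[re]:
                            minid[re] = minid[rd]
                            minpar[re] = minpar[rd] ^ lnk
                        # merged component is always nontrivial
                        n2_total += cnt1[re] if minpar[re] == 0 else cnt0[re]
                        npk_total += 1
            if not ok:
                while utop > ustart[pos]:
                    utop -= 1
                    ch = ulog_child[utop]
                    rt = ulog_root[utop]
                    parent[ch] = ch
                    par[ch] = 0
                    minid[rt] = ulog_minid[utop]
                    minpar[rt] = ulog_minpar[utop]
                    cnt0[rt] = ulog_cnt0[utop]
                    cnt1[rt] = ulog_cnt1[utop]
                    n2_total = ulog_n2[utop]
                    npk_total = ulog_npk[utop]
                continue
            pr_i[top] = pos
            pr_j[top] = j
            partner[pos] = j
            partner[j] = pos
            esum += ce[k]
            top += 1
            lv_choice[pos] = k
            qmark[pos] = q
            going_down = True
            pos += 1
            advanced = True
            break
        if advanced:
            continue
        lv_choice[pos] = -2
        pos -= 1

    inv_q = 1.0 / q
    P1 = np.zeros((n, n), dtype=np.float64)
    for a in range(n):
        for b in range(a + 1, n):
            v = P[a, b] * inv_q
            P[a, b] = v
            P[b, a] = v
            v2 = P2[a, b] * inv_q  # accumulated on (i < j) entries only
            P2[a, b] = v2
            P2[b, a] = v2
            v1 = v - v2
            if v1 < 0.0:
                v1 = 0.0
            P1[a, b] = v1
            P1[b, a] = v1
    for a in range(n):
        rowsum = 0.0
        for b in range(n):
            rowsum += P[a, b]
        P[a, n] = 1.0 - rowsum
    return q, count, P, P1, P2, mfe_partner, mfe_page2, mfe_energy


# ---------------------------------------------------------------------------
# Nested (pseudoknot-free) dynamic programs
# ---------------------------------------------------------------------------

@njit(cache=True)
def nested_inside(n, bs, sinv):
    """Scaled inside partition function over non-crossing structures.

    ``bs[i, j]`` must hold b(i, j) / s**2 where b = exp(-e(i,j)/kbt), 0
    for disallowed pairs; ``sinv`` = 1/s is the scaled weight of one
    unpaired base.  Returns the (n+2, n+2) table ``Qs`` where
    ``Qs[i, j+1]`` covers segment [i, j] inclusive (empty segments = 1).
    The true partition function of the whole sequence is
    ``Qs[0, n] * s**n``; the scale cancels from all probability ratios
    and only keeps the table in double-precision range.
    """
    Qs = np.zeros((n + 2, n + 2), dtype=np.float64)
    for i in range(n + 2):
        Qs[i, i] = 1.0
    for length in range(1, n + 1):
        for i in range(0, n - length + 1):
            j = i + length - 1  # inclusive right end
            total = Qs[i, j] * sinv  # j unpaired
            for k in range(i, j - MIN_LOOP_SPAN + 1):
                if bs[k, j] > 0.0:
                    total += Qs[i, k] * bs[k, j] * Qs[k + 1, j]
            Qs[i, j + 1] = total
    return Qs


@njit(cache=True)
def nested_outside(n, bs, Qs):
    """Scaled outside quantities for nested pair probabilities.

    ``Qo[i, j]`` sums over structures on the positions outside segment
    [i, j]; pairs may enclose the segment but never cross into it.
    Conditioning on the innermost enclosing pair (h, l):

        Qo(i,j) = Q(0..i-1) * Q(j+1..n-1)
                + sum_{h<i, l>j} bs(h,l) * Qo(h,l) * Q(h+1..i-1) * Q(j+1..l-1)

    Computed for all 0 <= i <= j < n in O(n^4).
    """
    Qo = np.zeros((n, n), dtype=np.float64)
    for span in range(n - 1, -1, -1):  # wider segments first
        for i in range(0, n - span):
            j = i + span
            total = Qs[0, i] * Qs[j + 1, n]
            for h in range(0, i):
                for l in range(j + 1, n):
                    if bs[h, l] > 0.0:
                        total += bs[h, l] * Qo[h, l] * Qs[h + 1, i] * Qs[j + 1, l]
            Qo[i, j] = total
    return Qo


@njit(cache=True)
def nested_pair_probabilities(n, bs, Qs, Qo):
    """Equilibrium pair probabilities for the nested ensemble (augmented)."""
    P = np.zeros((n, n + 1), dtype=np.float64)
    qtot = Qs[0, n]
    for i in range(n):
        for j in range(i + MIN_LOOP_SPAN, n):
            if bs[i, j] > 0.0:
                pij = bs[i, j] * Qs[i + 1, j] * Qo[i, j] / qtot
                P[i, j] = pij
                P[j, i] = pij
    for i in range(n):
        row = 0.0
        for j in range(n):
            row += P[i, j]
        P[i, n] = 1.0 - row
    return P


@njit(cache=True)
def nested_mfe_matrix(n, emat):
    """Minimum energy of each segment over nested structures.

    ``emat[i, j]`` is the pair energy or +inf when disallowed.  Returns
    M where M[i, j+1] covers segment [i, j] inclusive (empty = 0).
    """
    M = np.zeros((n + 2, n + 2), dtype=np.float64)
    for length in range(1, n + 1):
        for i in range(0, n - length + 1):
            j = i + length - 1
            best = M[i, j]  # j unpaired
            for k in range(i, j - MIN_LOOP_SPAN + 1):
                if not np.isinf(emat[k, j]):
                    v = M[i, k] + emat[k, j] + M[k + 1, j]
                    if v < best:
                        best = v
            M[i, j + 1] = best
    return M
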