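"""Numba kernels for the context-model stores and the mixture coder.

Storage layout
--------------
Every model memory is a context -> 4-counter table in one of three layouts:

* ``kind 0`` (dense): counts indexed directly by the 2-bit-packed context,
  used for shallow models (4**k small enough to allocate).
* ``kind 1`` (open hash): open addressing with linear probing over a table
  sized so that it can never fill; no eviction.
* ``kind 2`` (cache-hash): the table is split into buckets of ``B`` slots
  (bucket = 64-bit mix of the packed context, modulo the bucket count).
  Probing is open addressing inside the bucket; when a bucket is full the
  oldest entry (FIFO by insertion) is evicted and the bucket re-packed, so
  each bucket retains at most the ``B`` most recent contexts.

All stores for one coding pass live in flat numpy buffers (``dbuf`` for dense
counts; ``hkeys``/``hcnt``/``hage``/``hbfill`` for hashed stores) with
per-store offsets, which keeps the kernels free of python objects.

The packed context of an order-``k`` model fits in ``2k`` bits (k <= 20 is
40 bits), so the packed value itself is the exact hash key.
"""

from __future__ import annotations

import numpy as np
from numba import njit

U64 = np.uint64
WEIGHT_FLOOR = 1e-12

# ---------------------------------------------------------------------------
# hashing


@njit(cache=True, inline="always")
def _mix64(key):
    """SplitMix64 finalizer: 64-bit avalanche of the packed context."""
    z = U64(key)
    z = (z + U64(0x9E3779B97F4A7C15)) & U64(0xFFFFFFFFFFFFFFFF)
    z = (z ^ (z >> U64(30))) * U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> U64(27))) * U64(0x94D049BB133111EB)
    z = z ^ (z >> U64(31))
    return z


@njit(cache=True, inline="always")
def _u_find(hkeys, off, cap, key):
    """Open-addressing lookup; returns absolute slot or -1."""
    h = _mix64(key)
    i = np.int64(h & U64(cap - 1))
    while True:
        s = off + i
        kk = hkeys[s]
        if kk == key:
            return s
        if kk == -1:
            return np.int64(-1)
        i = (i + 1) & (cap - 1)


@njit(cache=True)
def _u_upsert(hkeys, hcnt, off, cap, key):
    """Find or claim a slot for ``key`` (counts zeroed on claim)."""
    h = _mix64(key)
    i = np.int64(h & U64(cap - 1))
    while True:
        s = off + i
        kk = hkeys[s]
        if kk == key:
            return s
        if kk == -1:
            hkeys[s] = key
            c = s * 4
            hcnt[c] = 0
            hcnt[c + 1] = 0
            hcnt[c + 2] = 0
            hcnt[c + 3] = 0
            return s
        i = (i + 1) & (cap - 1)


@njit(cache=True, inline="always")
def _b_find(hkeys, off, nbuckets, B, key):
    """Cache-hash lookup; returns absolute slot or -1."""
    h = _mix64(key)
    b = np.int64(h & U64(nbuckets - 1))
    start = np.int64((h >> U64(32)) % U64(B))
    base = off + b * B
    for j in range(B):
        s = base + ((start + j) % B)
        kk = hkeys[s]
        if kk == key:
            return s
        if kk == -1:
            return np.int64(-1)
    return np.int64(-1)


@njit(cache=True)
def _b_upsert(hkeys, hcnt, hage, hbfill, hctr, sid, off, boff, nbuckets, B, key):
    """Find or insert ``key`` in a cache-hash store, evicting FIFO if needed."""
    h = _mix64(key)
    b = np.int64(h & U64(nbuckets - 1))
    start = np.int64((h >> U64(32)) % U64(B))
    base = off + b * B
    empty = np.int64(-1)
    for j in range(B):
        s = base + ((start + j) % B)
        kk = hkeys[s]
        if kk == key:
            return s
        if kk == -1:
            empty = s
            break
    fidx = boff + b
    if hbfill[fidx] < B:
        s = empty
        hkeys[s] = key
        c = s * 4
        hcnt[c] = 0
        hcnt[c + 1] = 0
        hcnt[c + 2] = 0
        hcnt[c + 3] = 0
        hage[s] = hctr[sid]
        hctr[sid] += 1
        hbfill[fidx] += 1
        return s
    # bucket full: evict the oldest entry and re-pack the bucket
    vict = base
    amin = hage[base]
    for j in range(1, B):
        if hage[base + j] < amin:
            amin = hage[base + j]
            vict = base + j
    tk = np.empty(B, np.int64)
    tc = np.empty((B, 4), np.int32)
    ta = np.empty(B, np.int64)
    cnt = 0
    for j in range(B):
        s = base + j
        if s != vict and hkeys[s] != -1:
            tk[cnt] = hkeys[s]
            ta[cnt] = hage[s]
            for q in range(4):
                tc[cnt, q] = hcnt[s * 4 + q]
            cnt += 1
        hkeys[s] = -1
    hbfill[fidx] = cnt
    for t in range(cnt):
        h2 = _mix64(tk[t])
        st2 = np.int64((h2 >> U64(32)) % U64(B))
        for j in range(B):
            s = base + ((st2 + j) % B)
            if hkeys[s] == -1:
                hkeys[s] = tk[t]
                hage[s] = ta[t]
                for q in range(4):
                    hcnt[s * 4 + q] = tc[t, q]
                break
    for j in range(B):
        s = base + ((start + j) % B)
        if hkeys[s] == -1:
            hkeys[s] = key
            c = s * 4
            hcnt[c] = 0
            hcnt[c + 1] = 0
            hcnt[c + 2] = 0
            hcnt[c + 3] = 0
            hage[s] = hctr[sid]
            hctr[sid] += 1
            hbfill[fidx] += 1
            return s
    return np.int64(-1)  # unreachable: bucket had a free slot after eviction


# ---------------------------------------------------------------------------
# store access


@njit(cache=True, inline="always")
def _fetch(kind, sid, ctx, dbuf, doff, hkeys, hcnt, hoff, hnb, hB, hcap):
    """Counts (c0, c1, c2, c3) for a context; zeros if absent."""
    if kind == 0:
        b = doff[sid] + (ctx << 2)
        return dbuf[b], dbuf[b + 1], dbuf[b + 2], dbuf[b + 3]
    if kind == 1:
        slot = _u_find(hkeys, hoff[sid], hcap[sid], ctx)
    else:
        slot = _b_find(hkeys, hoff[sid], hnb[sid], hB[sid], ctx)
    if slot < 0:
        return np.int32(0), np.int32(0), np.int32(0), np.int32(0)
    c = slot * 4
    return hcnt[c], hcnt[c + 1], hcnt[c + 2], hcnt[c + 3]


@njit(cache=True, inline="always")
def _incr(kind, sid, ctx, sym, dbuf, doff, hkeys, hcnt, hage, hbfill, hctr, hoff, hboff, hnb, hB, hcap):
    """Increment count[ctx][sym] by one, inserting the context if new."""
    if kind == 0:
        dbuf[doff[sid] + (ctx << 2) + sym] += 1
        return
    if kind == 1:
        slot = _u_upsert(hkeys, hcnt, hoff[sid], hcap[sid], ctx)
    else:
        slot = _b_upsert(hkeys, hcnt, hage, hbfill, hctr, sid, hoff[sid], hboff[sid], hnb[sid], hB[sid], ctx)
    hcnt[slot * 4 + sym] += 1


# ---------------------------------------------------------------------------
# passes


@njit(cache=True)
def count_pass(sympad, kmax, ks, irs, kinds, sids, masks,
               dbuf, doff, hkeys, hcnt, hage, hbfill, hctr, hoff, hboff, hnb, hB, hcap):
    """Training pass: stream a sequence through plain-model count updates only.

    ``sympad`` is the symbol array left-padded with ``kmax`` zeros (symbol A),
    so the first positions of every model see an all-A context.  Models with
    the inverted-repeats flag additionally count the reverse complement of
    each (k+1)-mer window.
    """
    n = sympad.shape[0] - kmax
    M = ks.shape[0]
    ctx = np.zeros(M, np.int64)
    rc = np.empty(M, np.int64)
    for m in range(M):
        rc[m] = masks[m]
    for i in range(n):
        s = np.int64(sympad[kmax + i])
        for m in range(M):
            k = ks[m]
            _incr(kinds[m], sids[m], ctx[m], s, dbuf, doff,
                  hkeys, hcnt, hage, hbfill, hctr, hoff, hboff, hnb, hB, hcap)
            if irs[m]:
                rcn = ((3 - s) << (2 * (k - 1))) | (rc[m] >> 2)
                w1 = np.int64(sympad[kmax + i - k])
                _incr(kinds[m], sids[m], rcn, 3 - w1, dbuf, doff,
                      hkeys, hcnt, hage, hbfill, hctr, hoff, hboff, hnb, hB, hcap)
                rc[m] = rcn
            ctx[m] = ((ctx[m] << 2) | s) & masks[m]


@njit(cache=True)
def code_pass(sympad, kmax, ks, alphas, irs, tols, pairs, kinds, sids, masks,
              dbuf, doff, hkeys, hcnt, hage, hbfill, hctr, hoff, hboff, hnb, hB, hcap,
              w, gamma, do_update, bits_out):
    """One adaptive (or read-only) coding pass of the model mixture.

    Per symbol: each model predicts from its context with the alpha-smoothed
    estimator ``P(s) = (n_s + a) / (sum n + 4a)``; the blended probability
    uses the weights as they stood before the symbol; the ideal code length
    ``-log2 P`` is recorded; the weights update ``w_m <- norm(w_m**gamma *
    P_m(s))`` with a floor; finally (unless frozen) the plain-model counts
    update, and the tolerant-model private histories always advance.

    Returns ``(total_bits, max |1 - sum_s P(s)|, max |1 - sum_m w_m|)``.
    """
    n = sympad.shape[0] - kmax
    M = ks.shape[0]
    ctx = np.zeros(M, np.int64)
    rc = np.empty(M, np.int64)
    th = np.zeros(M, np.int64)
    miss = np.zeros(M, np.int64)
    for m in range(M):
        rc[m] = masks[m]
    pm = np.empty(M, np.float64)
    am_ = np.zeros(M, np.int64)
    total = 0.0
    max_perr = 0.0
    max_werr = 0.0
    for i in range(n):
        s = np.int64(sympad[kmax + i])
        psum = 0.0
        wsum = 0.0
        for m in range(M):
            a = alphas[m]
            if tols[m] == 0:
                cx = ctx[m]
            else:
                cx = th[m]
            c0, c1, c2, c3 = _fetch(kinds[m], sids[m], cx, dbuf, doff,
                                    hkeys, hcnt, hoff, hnb, hB, hcap)
            tot = np.float64(c0) + np.float64(c1) + np.float64(c2) + np.float64(c3)
            denom = tot + 4.0 * a
            if s == 0:
                cs = np.float64(c0)
            elif s == 1:
                cs = np.float64(c1)
            elif s == 2:
                cs = np.float64(c2)
            else:
                cs = np.float64(c3)
            pm[m] = (cs + a) / denom
            psum += w[m] * (((np.float64(c0) + a) + (np.float64(c1) + a)
                             + (np.float64(c2) + a) + (np.float64(c3) + a)) / denom)
            wsum += w[m]
            if tols[m] > 0:
                # argmax of the shared counts, ties broken A < C < G < T
                am = 0
                bc = c0
                if c1 > bc:
                    am = 1
                    bc = c1
                if c2 > bc:
                    am = 2
                    bc = c2
                if c3 > bc:
                    am = 3
                am_[m] = am
        P = 0.0
        for m in range(M):
            P += w[m] * pm[m]
        bits = -np.log2(P)
        bits_out[i] = bits
        total += bits
        perr = abs(psum - 1.0)
        if perr > max_perr:
            max_perr = perr
        werr = abs(wsum - 1.0)
        if werr > max_werr:
            max_werr = werr
        # weight update (exponential forgetting), then floor + renormalize
        tw = 0.0
        for m in range(M):
            w[m] = (w[m] ** gamma) * pm[m]
            tw += w[m]
        for m in range(M):
            w[m] /= tw
        tw = 0.0
        for m in range(M):
            if w[m] < WEIGHT_FLOOR:
                w[m] = WEIGHT_FLOOR
            tw += w[m]
        for m in range(M):
            w[m] /= tw
        # plain-model memory updates and true-context advance
        for m in range(M):
            if tols[m] == 0:
                k = ks[m]
                if do_update:
                    _incr(kinds[m], sids[m], ctx[m], s, dbuf, doff,
                          hkeys, hcnt, hage, hbfill, hctr, hoff, hboff, hnb, hB, hcap)
                    if irs[m]:
                        rcn = ((3 - s) << (2 * (k - 1))) | (rc[m] >> 2)
                        w1 = np.int64(sympad[kmax + i - k])
                        _incr(kinds[m], sids[m], rcn, 3 - w1, dbuf, doff,
                              hkeys, hcnt, hage, hbfill, hctr, hoff, hboff, hnb, hB, hcap)
                        rc[m] = rcn
                ctx[m] = ((ctx[m] << 2) | s) & masks[m]
        # tolerant private histories advance even when memories are frozen
        for m in range(M):
            if tols[m] > 0:
                if s == am_[m]:
                    th[m] = ((th[m] << 2) | s) & masks[m]
                else:
                    th[m] = ((th[m] << 2) | am_[m]) & masks[m]
                    miss[m] += 1
                    if miss[m] > tols[m]:
                        th[m] = ctx[pairs[m]]  # true past, current symbol included
                        miss[m] = 0
    return total, max_perr, max_werr


# single-store wrappers used by the python-level ModelMemory ---------------


@njit(cache=True)
def mem_fetch(kind, ctx, dbuf, doff, hkeys, hcnt, hoff, hnb, hB, hcap):
    return _fetch(kind, 0, ctx, dbuf, doff, hkeys, hcnt, hoff, hnb, hB, hcap)


@njit(cache=True)
def mem_incr(kind, ctx, sym, dbuf, doff, hkeys, hcnt, hage, hbfill, hctr, hoff, hboff, hnb, hB, hcap):
    _incr(kind, 0, ctx, sym, dbuf, doff, hkeys, hcnt, hage, hbfill, hctr, hoff, hboff, hnb, hB, hcap)


def next_pow2(n: int) -> int:
    """Smallest power of two >= max(n, 1)."""
    n = max(int(n), 1)
    return 1 << (n - 1).bit_length()
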