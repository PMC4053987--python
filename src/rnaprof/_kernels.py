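"""Numba kernels for the banded inside-outside dynamic program.

Coordinate convention (gap indices): DP index ``k`` in ``0..N`` denotes the
boundary before base ``k+1``; a state spanning ``(i, j]`` covers 1-based
bases ``i+1..j``.  Banded tables are indexed ``[i, d]`` with ``d = j - i``.
``Stem(i, j)`` assumes the pair ``(i+1, j)`` (1-based), i.e. 0-based
sequence positions ``(i, j-1)``.

Numerical scheme: every transition weight is pre-multiplied by
``exp(-eta * bases_emitted)`` so banded inside entries carry an implicit
``exp(+eta * span)`` rescaling, while the exterior (Outer) chains are kept
in log space.  Banded outside entries are stored divided by the partition
function (and rescaled by ``exp(+eta * span)``), so every inside x outside
product used by the readout is a probability directly.
"""

import numpy as np
from numba import njit

__all__ = ["inside_kernel", "outside_kernel", "profile_kernel"]


@njit(cache=True, inline="always")
def _bx(codes, k):
    """Mismatch-table index of the base at 0-based position k (N -> 0)."""
    c = codes[k]
    if c >= 4:
        return 0
    return c + 1


@njit(cache=True, inline="always")
def _hp_w(codes, i0, j0, PT, whp_len, wmmh, wterm, skeys, svals):
    """Scaled hairpin weight for closing pair at 0-based (i0, j0)."""
    L = j0 - i0 - 1
    pt = PT[codes[i0], codes[j0]]
    if pt < 0 or L < 3:
        return 0.0
    if skeys.size > 0 and (L == 3 or L == 4 or L == 6):
        ok = True
        key = np.int64(L)
        for t in range(i0, j0 + 1):
            c = codes[t]
            if c >= 4:
                ok = False
                break
            key = key * 4 + c
        if ok:
            idx = np.searchsorted(skeys, key)
            if idx < skeys.size and skeys[idx] == key:
                return svals[idx]
    w = whp_len[L]
    if L == 3:
        w *= wterm[pt]
    else:
        w *= wmmh[pt, _bx(codes, i0 + 1), _bx(codes, j0 - 1)]
    return w


@njit(cache=True, inline="always")
def _int_w(codes, i0, j0, p0, q0, PT, wbul, wintl, wasym, wmmi, west, wterm,
           wi11, wi21, wi22):
    """Scaled bulge/internal-loop weight between 0-based pairs (i0,j0), (p0,q0).

    Geometry (m + n >= 1, cap) is assumed checked by the caller.
    """
    m = p0 - i0 - 1
    n = j0 - q0 - 1
    pt1 = PT[codes[i0], codes[j0]]
    pt2 = PT[codes[q0], codes[p0]]
    if pt1 < 0 or pt2 < 0:
        return 0.0
    L = m + n
    if m == 0 or n == 0:
        w = wbul[L]
        if L == 1:
            w *= west[pt1, pt2]
        else:
            w *= wterm[pt1] * wterm[pt2]
        return w
    if m == 1 and n == 1:
        return wi11[pt1, pt2, _bx(codes, i0 + 1), _bx(codes, j0 - 1)]
    if m == 1 and n == 2:
        return wi21[pt1, pt2, _bx(codes, i0 + 1), _bx(codes, q0 + 1),
                    _bx(codes, j0 - 1)]
    if m == 2 and n == 1:
        return wi21[pt2, pt1, _bx(codes, q0 + 1), _bx(codes, i0 + 1),
                    _bx(codes, p0 - 1)]
    if m == 2 and n == 2:
        a = codes[i0 + 1]
        b = codes[p0 - 1]
        c = codes[q0 + 1]
        d = codes[j0 - 1]
        if a < 4 and b < 4 and c < 4 and d < 4:
            return wi22[pt1, pt2, a, b, c, d]
    return (wintl[L] * wasym[abs(m - n)]
            * wmmi[pt1, _bx(codes, i0 + 1), _bx(codes, j0 - 1)]
            * wmmi[pt2, _bx(codes, q0 + 1), _bx(codes, p0 - 1)])


@njit(cache=True)
def inside_kernel(codes, W, C, eta, PT, TW):
    (wstack, wse, whp_len, wmmh, wterm, skeys, svals, wbul, wintl, wasym,
     wmmi, west, wi11, wi21, wi22, wml_close, wml_branch, wml_unp,
     wext) = TW
    N = codes.size
    aS = np.zeros((N + 1, W + 1))
    aSE = np.zeros((N + 1, W + 1))
    aM = np.zeros((N + 1, W + 1))
    aMB = np.zeros((N + 1, W + 1))
    aM1 = np.zeros((N + 1, W + 1))
    aM2 = np.zeros((N + 1, W + 1))
    for d in range(W + 1):
        for i in range(N - d + 1):
            j = i + d
            if d >= 5:
                # Stem(i,j): pair (i+1, j) = 0-based (i, j-1)
                pt = PT[codes[i], codes[j - 1]]
                if pt >= 0:
                    v = aSE[i + 1, d - 2] * wse
                    if d >= 7:
                        ptr = PT[codes[j - 2], codes[i + 1]]
                        if ptr >= 0:
                            v += aS[i + 1, d - 2] * wstack[pt, ptr]
                    aS[i, d] = v
                # MultiBif(i,j) = Multi1(i,k) . Multi2(k,j)
                if d >= 10:
                    s = 0.0
                    for k in range(i + 5, j - 4):
                        if aM1[i, k - i] > 0.0 and aM2[k, j - k] > 0.0:
                            s += aM1[i, k - i] * aM2[k, j - k]
                    aMB[i, d] = s
                # Multi2: Stem with trailing unpaired bases
                v = aM2[i, d - 1] * wml_unp
                if aS[i, d] > 0.0:
                    v += aS[i, d] * wml_branch[PT[codes[i], codes[j - 1]]]
                aM2[i, d] = v
                aM1[i, d] = aM2[i, d] + aMB[i, d]
                aM[i, d] = aM[i + 1, d - 1] * wml_unp + aMB[i, d]
            # StemEnd(i,j): enclosed by pair (i, j+1) = 0-based (i-1, j)
            if i >= 1 and j < N and d + 2 <= W and d >= 3:
                pt0 = PT[codes[i - 1], codes[j]]
                if pt0 >= 0:
                    v = _hp_w(codes, i - 1, j, PT, whp_len, wmmh, wterm,
                              skeys, svals)
                    mmax = min(C, d - 5)
                    for m in range(mmax + 1):
                        ip = i + m
                        nmax = min(C - m, d - 5 - m)
                        nmin = 1 if m == 0 else 0
                        for n in range(nmin, nmax + 1):
                            jp = j - n
                            av = aS[ip, jp - ip]
                            if av > 0.0:
                                v += av * _int_w(codes, i - 1, j, ip, jp - 1,
                                                 PT, wbul, wintl, wasym,
                                                 wmmi, west, wterm,
                                                 wi11, wi21, wi22)
                    if aM[i, d] > 0.0:
                        v += aM[i, d] * wml_close[pt0]
                    aSE[i, d] = v
    # Outer chain in log space (unscaled)
    la = np.full(N + 1, -np.inf)
    la[0] = 0.0
    buf = np.empty(W + 2)
    for i in range(1, N + 1):
        nt = 0
        buf[nt] = la[i - 1]
        nt += 1
        kmin = i - W
        if kmin < 0:
            kmin = 0
        for k in range(kmin, i - 4):
            a = aS[k, i - k]
            if a > 0.0:
                pt = PT[codes[k], codes[i - 1]]
                buf[nt] = la[k] + np.log(a) + eta * (i - k) + np.log(wext[pt])
                nt += 1
        mx = buf[0]
        for t in range(1, nt):
            if buf[t] > mx:
                mx = buf[t]
        s = 0.0
        for t in range(nt):
            s += np.exp(buf[t] - mx)
        la[i] = mx + np.log(s)
    return aS, aSE, aM, aMB, aM1, aM2, la


@njit(cache=True)
def outside_kernel(codes, W, C, eta, PT, TW, aS, aM1, aM2, la):
    (wstack, wse, whp_len, wmmh, wterm, skeys, svals, wbul, wintl, wasym,
     wmmi, west, wi11, wi21, wi22, wml_close, wml_branch, wml_unp,
     wext) = TW
    N = codes.size
    logZ = la[N]
    lb = np.full(N + 1, -np.inf)
    lb[N] = 0.0
    buf = np.empty(W + 2)
    for i in range(N - 1, -1, -1):
        nt = 0
        buf[nt] = lb[i + 1]
        nt += 1
        kmax = i + W
        if kmax > N:
            kmax = N
        for k in range(i + 5, kmax + 1):
            a = aS[i, k - i]
            if a > 0.0:
                pt = PT[codes[i], codes[k - 1]]
                buf[nt] = np.log(a) + eta * (k - i) + np.log(wext[pt]) + lb[k]
                nt += 1
        mx = buf[0]
        for t in range(1, nt):
            if buf[t] > mx:
                mx = buf[t]
        s = 0.0
        for t in range(nt):
            s += np.exp(buf[t] - mx)
        lb[i] = mx + np.log(s)

    bS = np.zeros((N + 1, W + 1))
    bSE = np.zeros((N + 1, W + 1))
    bM = np.zeros((N + 1, W + 1))
    bMB = np.zeros((N + 1, W + 1))
    bM1 = np.zeros((N + 1, W + 1))
    bM2 = np.zeros((N + 1, W + 1))
    for d in range(W, -1, -1):
        for i in range(N - d + 1):
            j = i + d
            under_pair = (i >= 1 and j < N and d + 2 <= W
                          and PT[codes[i - 1], codes[j]] >= 0)
            if under_pair and d >= 3:
                bSE[i, d] = bS[i - 1, d + 2] * wse
            if d >= 5:
                # Multi(i,j); the unpaired-extension chain is not gated on
                # (i-1, j) being a pair -- only the StemEnd entry point is
                v = 0.0
                if under_pair and bSE[i, d] > 0.0:
                    v += bSE[i, d] * wml_close[PT[codes[i - 1], codes[j]]]
                if i >= 1 and d + 1 <= W:
                    v += bM[i - 1, d + 1] * wml_unp
                bM[i, d] = v
            if d >= 5:
                # Multi1(i,j) from MultiBif(i,k) = Multi1(i,j) . Multi2(j,k)
                v = 0.0
                kmax = i + W
                if kmax > N:
                    kmax = N
                for k in range(j + 5, kmax + 1):
                    if bMB[i, k - i] > 0.0 and aM2[j, k - j] > 0.0:
                        v += bMB[i, k - i] * aM2[j, k - j]
                bM1[i, d] = v
                bMB[i, d] = bM1[i, d] + bM[i, d]
                # Multi2(i,j)
                v = bM1[i, d]
                if j < N and d + 1 <= W:
                    v += bM2[i, d + 1] * wml_unp
                kmin = j - W
                if kmin < 0:
                    kmin = 0
                for k in range(kmin, i - 4):
                    if bMB[k, j - k] > 0.0 and aM1[k, i - k] > 0.0:
                        v += bMB[k, j - k] * aM1[k, i - k]
                bM2[i, d] = v
                # Stem(i,j)
                if aS[i, d] > 0.0:
                    pt = PT[codes[i], codes[j - 1]]
                    v = np.exp(la[i] + lb[j] - logZ + eta * d) * wext[pt]
                    ipmin = i - C
                    if ipmin < 1:
                        ipmin = 1
                    for ip in range(ipmin, i + 1):
                        m = i - ip
                        for jp in range(j if m > 0 else j + 1, j + C - m + 1):
                            if jp > N - 1 or jp - ip + 2 > W:
                                break
                            bv = bSE[ip, jp - ip]
                            if bv > 0.0:
                                v += bv * _int_w(codes, ip - 1, jp, i, j - 1,
                                                 PT, wbul, wintl, wasym,
                                                 wmmi, west, wterm,
                                                 wi11, wi21, wi22)
                    if bM2[i, d] > 0.0:
                        v += bM2[i, d] * wml_branch[pt]
                    if i >= 1 and j < N and d + 2 <= W:
                        ptp = PT[codes[i - 1], codes[j]]
                        if ptp >= 0 and bS[i - 1, d + 2] > 0.0:
                            ptr = PT[codes[j - 1], codes[i]]
                            if ptr >= 0:
                                v += bS[i - 1, d + 2] * wstack[ptp, ptr]
                    bS[i, d] = v
    return bS, bSE, bM, bMB, bM1, bM2, lb


@njit(cache=True)
def profile_kernel(codes, W, C, eta, PT, TW, aS, aSE, aM, aM2, la,
                   bS, bSE, bM, bM2, lb):
    (wstack, wse, whp_len, wmmh, wterm, skeys, svals, wbul, wintl, wasym,
     wmmi, west, wi11, wi21, wi22, wml_close, wml_branch, wml_unp,
     wext) = TW
    N = codes.size
    logZ = la[N]
    prof = np.zeros((N, 6))  # columns B, E, H, I, M, S
    dH = np.zeros(N + 1)
    dB = np.zeros(N + 1)
    dI = np.zeros(N + 1)
    # exterior
    for i in range(1, N + 1):
        prof[i - 1, 1] = np.exp(la[i - 1] + lb[i] - logZ)
    # stem: decompose P(pair i+1, j) by what the pair closes
    for d in range(5, W + 1):
        for i in range(N - d + 1):
            j = i + d
            if aS[i, d] <= 0.0 or bS[i, d] <= 0.0:
                continue
            pt = PT[codes[i], codes[j - 1]]
            v = aSE[i + 1, d - 2] * wse
            if d >= 7:
                ptr = PT[codes[j - 2], codes[i + 1]]
                if ptr >= 0:
                    v += aS[i + 1, d - 2] * wstack[pt, ptr]
            P = bS[i, d] * v
            prof[i, 5] += P
            prof[j - 1, 5] += P
    # hairpin / bulge / internal via the loop-closing StemEnd states
    for d in range(3, W - 1):
        for i in range(1, N - d):
            j = i + d
            bv = bSE[i, d]
            if bv <= 0.0:
                continue
            hw = _hp_w(codes, i - 1, j, PT, whp_len, wmmh, wterm, skeys,
                       svals)
            if hw > 0.0:
                P = bv * hw
                dH[i] += P
                dH[j] -= P
            mmax = min(C, d - 5)
            for m in range(mmax + 1):
                ip = i + m
                nmax = min(C - m, d - 5 - m)
                nmin = 1 if m == 0 else 0
                for n in range(nmin, nmax + 1):
                    jp = j - n
                    av = aS[ip, jp - ip]
                    if av <= 0.0:
                        continue
                    P = bv * av * _int_w(codes, i - 1, j, ip, jp - 1, PT,
                                         wbul, wintl, wasym, wmmi, west,
                                         wterm, wi11, wi21, wi22)
                    if m == 0:
                        dB[jp] += P
                        dB[j] -= P
                    elif n == 0:
                        dB[i] += P
                        dB[ip] -= P
                    else:
                        dI[i] += P
                        dI[ip] -= P
                        dI[jp] += P
                        dI[j] -= P
    # multibranch unpaired emissions
    for i in range(1, N + 1):
        s = 0.0
        kmax = i - 1 + W
        if kmax > N:
            kmax = N
        for k in range(i + 5, kmax + 1):
            if bM[i - 1, k - i + 1] > 0.0 and aM[i, k - i] > 0.0:
                s += bM[i - 1, k - i + 1] * aM[i, k - i]
        kmin = i - W
        if kmin < 0:
            kmin = 0
        for k in range(kmin, i - 5):
            if bM2[k, i - k] > 0.0 and aM2[k, i - 1 - k] > 0.0:
                s += bM2[k, i - k] * aM2[k, i - 1 - k]
        prof[i - 1, 4] = s * wml_unp
    accH = 0.0
    accB = 0.0
    accI = 0.0
    for r in range(N):
        accH += dH[r]
        accB += dB[r]
        accI += dI[r]
        prof[r, 2] = accH
        prof[r, 0] = accB
        prof[r, 3] = accI
    return prof
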