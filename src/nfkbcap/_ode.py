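"""Right-hand side kernels for the CAR-4-1BB -> NFkB mass-action scheme.

Species layout (index into the state vector)::

    0  CAR        free chimeric antigen receptor
    1  AgCAR      antigen-bound receptor
    2  TRAF2      free adapter
    3  SIG        signalosome (AgCAR:TRAF2)
    4  RIP1       unmodified RIP1
    5  RIP1Ub     K63-ubiquitinated RIP1
    6  TAK        inactive TAK complex
    7  TAKa       active TAK
    8  IKKb       inactive (activatable) IKKbeta
    9  IKKba      catalytically active IKKbeta
    10 IKKbi      terminally auto-deactivated IKKbeta
    11 IkBa       free inhibitor
    12 CPLX       cytoplasmic IkBa:NFkB complex
    13 NFkBc      free cytoplasmic NFkB
    14 NFkBn      nuclear NFkB
    15 SIGi       inactivated (internalized) receptor complex; TRAF2 is
                  released back to the cytoplasm on inactivation

Rate-constant layout (index into the rate vector)::

    0  k_bind    Ag + CAR association (per (molec/um^2) per min)
    1  k_unbind  AgCAR dissociation
    2  k_sig     AgCAR + TRAF2 -> signalosome
    3  k_sigr    signalosome dissociation
    4  k_rip     signal handoff SIG + RIP1 -> SIGi + RIP1Ub (the
                 signalosome is spent ubiquitinating one RIP1)
    5  k_ripr    RIP1Ub reversal (deubiquitination) without handoff
    6  k_tak     handoff RIP1Ub + TAK -> RIP1 + TAKa
    7  k_takr    TAKa decay to TAK without handoff
    8  k_ikk     handoff TAKa + IKKb -> TAK + IKKba
    9  k_deact   IKKba first-order auto-deactivation (perturbable)
    10 k_deg     IKKba-catalyzed degradation of free IkBa
    11 k_degc    IKKba-catalyzed degradation of complexed IkBa
    12 k_bdeg    basal free-IkBa degradation
    13 k_cdeg    basal complex turnover (IkBa degraded, NFkB released)
    14 k_syn0    basal IkBa synthesis (ikba_scale folded in by caller)
    15 k_syn     NFkBn-driven IkBa synthesis (ikba_scale folded in)
    16 k_in      NFkB nuclear import
    17 k_ass     IkBa + NFkBc association
    18 k_exp     IkBa-mediated capture of nuclear NFkB into the complex
    19 k_sdeg    first-order signalosome inactivation (internalization /
                 receptor-complex turnover); makes the kinase drive
                 transient and dose-limited

All first-order constants are per minute; bimolecular constants are per
concentration-unit per minute.  The antigen surface density ``a`` is held
constant (no depletion of the target surface).

The kinase tier is a stoichiometric relay rather than a catalytic
amplifier: each signalosome ubiquitinates one RIP1 and is spent, each
RIP1Ub docks and activates one TAK, each active TAK phosphorylates one
IKKbeta.  The amount of active IKKbeta is therefore metered by the number
of receptor-routing events (dose-limited), while the RIP1/TAK/IKKbeta
pool sizes enter only through saturating branching fractions — which is
what keeps the pathway's dose sensitivity per cell stable under strong
abundance noise.
"""

from __future__ import annotations

import numpy as np

N_SPECIES = 16
N_RATES = 20

SPECIES = (
    "CAR", "AgCAR", "TRAF2", "SIG", "RIP1", "RIP1Ub", "TAK", "TAKa",
    "IKKb", "IKKba", "IKKbi", "IkBa", "CPLX", "NFkBc", "NFkBn", "SIGi",
)

RATE_NAMES = (
    "k_bind", "k_unbind", "k_sig", "k_sigr", "k_rip", "k_ripr",
    "k_tak", "k_takr", "k_ikk", "k_deact", "k_deg", "k_degc",
    "k_bdeg", "k_cdeg", "k_syn0", "k_syn", "k_in", "k_ass", "k_exp",
    "k_sdeg",
)


def _rhs_py(t, y, a, r):
    car, agcar, traf2, sig, rip1, rip1ub, tak, taka = y[0], y[1], y[2], y[3], y[4], y[5], y[6], y[7]
    ikkb, ikkba = y[8], y[9]
    ikba, cplx, nfkbc, nfkbn = y[11], y[12], y[13], y[14]

    r1 = r[0] * a * car - r[1] * agcar
    r2 = r[2] * agcar * traf2 - r[3] * sig
    r2b = r[19] * sig
    r3 = r[4] * sig * rip1
    r3r = r[5] * rip1ub
    r4 = r[6] * rip1ub * tak
    r4r = r[7] * taka
    r5 = r[8] * taka * ikkb
    r6 = r[9] * ikkba
    r7 = r[10] * ikkba * ikba
    r8 = r[11] * ikkba * cplx
    r9 = r[12] * ikba
    r10 = r[13] * cplx
    r11 = r[14] + r[15] * nfkbn
    r12 = r[16] * nfkbc
    r13 = r[17] * ikba * nfkbc
    r14 = r[18] * ikba * nfkbn

    dy = np.empty(16)
    dy[0] = -r1
    dy[1] = r1 - r2
    dy[2] = -r2 + r2b + r3
    dy[3] = r2 - r2b - r3
    dy[15] = r2b + r3
    dy[4] = -r3 + r3r + r4
    dy[5] = r3 - r3r - r4
    dy[6] = -r4 + r4r + r5
    dy[7] = r4 - r4r - r5
    dy[8] = -r5
    dy[9] = r5 - r6
    dy[10] = r6
    dy[11] = r11 - r9 - r7 - r13 - r14
    dy[12] = r13 + r14 - r8 - r10
    dy[13] = r8 + r10 - r12 - r13
    dy[14] = r12 - r14
    return dy


def _jac_py(t, y, a, r):
    """Analytic Jacobian of the RHS (speeds up the stiff solver)."""
    car, agcar, traf2, sig = y[0], y[1], y[2], y[3]
    rip1, rip1ub, tak, taka = y[4], y[5], y[6], y[7]
    ikkb, ikkba = y[8], y[9]
    ikba, cplx, nfkbc, nfkbn = y[11], y[12], y[13], y[14]

    J = np.zeros((16, 16))
    # r1 = k_bind*a*CAR - k_unbind*AgCAR
    J[0, 0] -= r[0] * a; J[0, 1] += r[1]
    J[1, 0] += r[0] * a; J[1, 1] -= r[1]
    # r2 = k_sig*AgCAR*TRAF2 - k_sigr*SIG
    d_ag = r[2] * traf2; d_t2 = r[2] * agcar
    for i, s_ in ((1, -1.0), (2, -1.0), (3, 1.0)):
        J[i, 1] += s_ * d_ag; J[i, 2] += s_ * d_t2; J[i, 3] += -s_ * r[3]
    # r2b = k_sdeg*SIG (TRAF2 released)
    J[3, 3] -= r[19]; J[15, 3] += r[19]; J[2, 3] += r[19]
    # r3 = k_rip*SIG*RIP1 (SIG+RIP1 -> SIGi+RIP1Ub), r3r = k_ripr*RIP1Ub
    d_sig = r[4] * rip1; d_rip = r[4] * sig
    J[3, 3] -= d_sig; J[3, 4] -= d_rip
    J[15, 3] += d_sig; J[15, 4] += d_rip
    J[2, 3] += d_sig; J[2, 4] += d_rip
    J[4, 3] -= d_sig; J[4, 4] -= d_rip; J[4, 5] += r[5]
    J[5, 3] += d_sig; J[5, 4] += d_rip; J[5, 5] -= r[5]
    # r4 = k_tak*RIP1Ub*TAK (RIP1Ub+TAK -> RIP1+TAKa), r4r = k_takr*TAKa
    d_ub = r[6] * tak; d_tak = r[6] * rip1ub
    J[4, 5] += d_ub; J[4, 6] += d_tak
    J[5, 5] -= d_ub; J[5, 6] -= d_tak
    J[6, 5] -= d_ub; J[6, 6] -= d_tak; J[6, 7] += r[7]
    J[7, 5] += d_ub; J[7, 6] += d_tak; J[7, 7] -= r[7]
    # r5 = k_ikk*TAKa*IKKb (TAKa+IKKb -> TAK+IKKba)
    d_ta = r[8] * ikkb; d_ik = r[8] * taka
    J[6, 7] += d_ta; J[6, 8] += d_ik
    J[7, 7] -= d_ta; J[7, 8] -= d_ik
    J[8, 7] -= d_ta; J[8, 8] -= d_ik
    J[9, 7] += d_ta; J[9, 8] += d_ik
    # r6 = k_deact*IKKba
    J[9, 9] -= r[9]; J[10, 9] += r[9]
    # r7 = k_deg*IKKba*IkBa
    J[11, 9] -= r[10] * ikba; J[11, 11] -= r[10] * ikkba
    # r8 = k_degc*IKKba*CPLX
    d_ik8 = r[11] * cplx; d_c8 = r[11] * ikkba
    J[12, 9] -= d_ik8; J[12, 12] -= d_c8
    J[13, 9] += d_ik8; J[13, 12] += d_c8
    # r9 = k_bdeg*IkBa
    J[11, 11] -= r[12]
    # r10 = k_cdeg*CPLX
    J[12, 12] -= r[13]; J[13, 12] += r[13]
    # r11 = k_syn0 + k_syn*NFkBn
    J[11, 14] += r[15]
    # r12 = k_in*NFkBc
    J[13, 13] -= r[16]; J[14, 13] += r[16]
    # r13 = k_ass*IkBa*NFkBc
    d_i13 = r[17] * nfkbc; d_n13 = r[17] * ikba
    J[11, 11] -= d_i13; J[11, 13] -= d_n13
    J[12, 11] += d_i13; J[12, 13] += d_n13
    J[13, 11] -= d_i13; J[13, 13] -= d_n13
    # r14 = k_exp*IkBa*NFkBn
    d_i14 = r[18] * nfkbn; d_n14 = r[18] * ikba
    J[11, 11] -= d_i14; J[11, 14] -= d_n14
    J[12, 11] += d_i14; J[12, 14] += d_n14
    J[14, 11] -= d_i14; J[14, 14] -= d_n14
    return J


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    rhs = njit(cache=True)(_rhs_py)
    jac = njit(cache=True)(_jac_py)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    rhs = _rhs_py
    jac = _jac_py
    HAVE_NUMBA = False


def nfkb_subsystem_rhs(t, y, kb, kc, s0, s1, ki, ka, ke, ntot):
    """Reduced pre-stimulation subsystem (IkBa, NFkBc, NFkBn); CPLX by conservation."""
    ikba, nfkbc, nfkbn = y
    cplx = ntot - nfkbc - nfkbn
    r9 = kb * ikba
    r10 = kc * cplx
    r11 = s0 + s1 * nfkbn
    r12 = ki * nfkbc
    r13 = ka * ikba * nfkbc
    r14 = ke * ikba * nfkbn
    return np.array([
        r11 - r9 - r13 - r14,
        r10 - r12 - r13,
        r12 - r14,
    ])
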