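"""Joint minimization of structure energy and codon cost over a codon lattice.

The design problem: among all synonymous CDSs of a protein and all
pseudoknot-free secondary structures of each, find the pair minimizing

    mu * E(structure)  +  kappa * sum(-ln w(codon))

which, by ``l*log(CAI) = sum(ln w)``, covers both published scalarizations:
``MFE - lambda_LD * l * log(CAI)`` (``mu=1, kappa=lambda_LD``) and
``lambda_DN * MFE - (1 - lambda_DN) * l * log(CAI)`` (``mu=lambda_DN,
kappa=1-lambda_DN``).

The solver is a span-based Zuker-style dynamic program whose cells are
indexed by *pairs of lattice variant states* at the span boundaries instead
of plain positions, so each cell is a small (<=6 x 6) matrix combined with
min-plus products.  The codon cost ``kappa * (-ln w)`` is charged exactly
once per codon, on the edge entering its third-position state.  Exact mode
explores everything in O(L^3) time / O(L^2) space for bounded lattice width;
beam mode keeps only the ``b`` best entries of the pairing matrices per
right endpoint, yielding a feasible (upper-bound) design.

``fold_fixed`` folds a fixed RNA sequence by running the same machinery on
a degenerate single-path lattice with ``kappa = 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .codon_model import RNA_ALPHABET
from .energy import PAIR_INDEX, PAIR_ORDER, EnergyModel, score_structure
from .lattice import CodonLattice, LatticeState

__all__ = ["Objective", "DesignResult", "design", "fold_fixed"]

INF = np.inf
MAXLOOP = 30  # largest bulge/internal loop enumerated by the DP
# index of the reversed pair: CG<->GC, GU<->UG, AU<->UA
_REV = np.array([1, 0, 3, 2, 5, 4])


@dataclass(frozen=True)
class Objective:
    """A scalarization of the (MFE, CAI) bi-objective.

    ``linear_design``: minimize ``MFE - lam * l * log(CAI)``, ``lam >= 0``.
    ``derna``:         minimize ``lam * MFE - (1-lam) * l * log(CAI)``,
    ``lam`` in [0, 1].
    """

    formulation: str
    lam: float

    def __post_init__(self) -> None:
        if self.formulation == "linear_design":
            if self.lam < 0:
                raise ValueError("linear_design lambda must be >= 0")
        elif self.formulation == "derna":
            if not 0.0 <= self.lam <= 1.0:
                raise ValueError("derna lambda must be in [0, 1]")
        else:
            raise ValueError(f"unknown formulation {self.formulation!r}")

    @property
    def mu(self) -> float:
        return 1.0 if self.formulation == "linear_design" else self.lam

    @property
    def kappa(self) -> float:
        return self.lam if self.formulation == "linear_design" else 1.0 - self.lam

    def value(self, mfe: float, S: float) -> float:
        """Objective value of a design with energy ``mfe`` and ``S=sum(ln w)``."""
        return self.mu * mfe - self.kappa * S


@dataclass(frozen=True)
class DesignResult:
    """One designed CDS with its structure and both objective components."""

    cds: str
    structure: str
    mfe: float
    S: float  # sum of ln w over codons = l * ln(CAI)
    cai: float
    objective_value: float
    lambda_used: float
    formulation: str
    exact: bool

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3


class _LatticeFolder:
    """Shared DP engine for nussinov and nearest-neighbor models."""

    def __init__(
        self,
        lattice: CodonLattice,
        model: EnergyModel,
        mu: float,
        kappa: float,
        beam: int | None = None,
    ):
        if lattice.length == 0:
            raise ValueError("empty lattice")
        if beam is not None and beam < 1:
            raise ValueError("beam width must be >= 1")
        self.model = model
        self.mu = mu
        self.beam = beam
        self.L = lattice.length
        self.n = [len(layer) for layer in lattice.states]
        self.nucs = [[s.nuc for s in layer] for layer in lattice.states]
        self.ops = 0  # split-point evaluations (complexity bookkeeping)

        # edge matrices: E[i][a, b] = kappa * (-ln w) charged on entering b
        self.E: list[np.ndarray] = []
        for i in range(self.L - 1):
            ni, nj = self.n[i], self.n[i + 1]
            adj = np.zeros((ni, nj), dtype=bool)
            for a, b in lattice.transitions(i):
                adj[a, b] = True
            wcol = np.array(
                [kappa * s.neg_log_w for s in lattice.states[i + 1]]
            )
            self.E.append(np.where(adj, wcol[None, :], INF))

        # pair-type matrices per span, and the symmetric stacking table
        self._pt: dict[tuple[int, int], np.ndarray] = {}
        self._au: dict[tuple[int, int], np.ndarray] = {}
        self.SY = np.zeros((6, 6))
        if model.stack_table:
            for x, px in enumerate(PAIR_ORDER):
                for y, py in enumerate(PAIR_ORDER):
                    v = model.stack_table.get((px, py))
                    if v is None:
                        v = model.stack_table[(py, px)]
                    self.SY[x, y] = v

        self.P: dict[tuple[int, int], np.ndarray] = {}
        self.C: dict[tuple[int, int], np.ndarray] = {}
        self.B: dict[tuple[int, int], np.ndarray] = {}  # nussinov any-structure
        self.M: dict[tuple[int, int], np.ndarray] = {}  # multiloop, >=1 branch
        self.M1: dict[tuple[int, int], np.ndarray] = {}  # multiloop, 1st branch at i
        self.F: list[np.ndarray] = []  # external loop, prefix DP

    # -- small helpers ------------------------------------------------------

    def pt(self, i: int, j: int) -> np.ndarray:
        key = (i, j)
        if key not in self._pt:
            mat = np.full((self.n[i], self.n[j]), -1, dtype=int)
            au = np.zeros((self.n[i], self.n[j]))
            for a, x in enumerate(self.nucs[i]):
                for b, y in enumerate(self.nucs[j]):
                    idx = PAIR_INDEX.get(x + y, -1)
                    mat[a, b] = idx
                    if idx >= 0:
                        au[a, b] = self.model.au_end(x + y)
            self._pt[key] = mat
            self._au[key] = au
        return self._pt[key]

    def au(self, i: int, j: int) -> np.ndarray:
        self.pt(i, j)
        return self._au[(i, j)]

    @staticmethod
    def _mp(A: np.ndarray, B: np.ndarray) -> np.ndarray:
        """Min-plus product of two boundary-state matrices."""
        return np.min(A[:, :, None] + B[None, :, :], axis=1)

    def _path(self, i: int, j: int) -> np.ndarray:
        """P[i, j]: cheapest codon-cost walk i -> j (weights charged on (i, j])."""
        return self.P[(i, j)]

    def _precompute_paths(self) -> None:
        for i in range(self.L):
            self.P[(i, i)] = np.where(np.eye(self.n[i], dtype=bool), 0.0, INF)
        for span in range(1, self.L):
            for i in range(self.L - span):
                j = i + span
                self.P[(i, j)] = self._mp(self.P[(i, j - 1)], self.E[j - 1])

    def _prune_column(self, mat: dict[tuple[int, int], np.ndarray], j: int) -> None:
        if self.beam is None:
            return
        entries = []
        for (i, jj), arr in mat.items():
            if jj != j:
                continue
            for u in range(arr.shape[0]):
                for v in range(arr.shape[1]):
                    if np.isfinite(arr[u, v]):
                        entries.append((arr[u, v], i, u, v))
        if len(entries) <= self.beam:
            return
        entries.sort()
        for val, i, u, v in entries[self.beam :]:
            mat[(i, j)][u, v] = INF

    # -- forward pass -------------------------------------------------------

    def solve(self, trace: bool = True):
        self._precompute_paths()
        if self.model.name == "nussinov":
            value = self._forward_nussinov()
        else:
            value = self._forward_turner()
        if not trace:
            return value, None, None
        assign, pairs = self._traceback()
        return value, assign, pairs

    # .. nussinov ..

    def _forward_nussinov(self) -> float:
        mu, E = self.mu, self.E
        for j in range(self.L):
            for i in range(j - 4, -1, -1):
                pt = self.pt(i, j)
                inner = self._mp(self._mp(E[i], self.B[(i + 1, j - 1)]), E[j - 1])
                self.C[(i, j)] = np.where(pt >= 0, mu * self.model.pair_bonus + inner, INF)
            self._prune_column(self.C, j)
            for i in range(j, -1, -1):
                if i == j:
                    self.B[(i, j)] = self.P[(i, i)].copy()
                    continue
                best = self._mp(self.B[(i, j - 1)], E[j - 1])
                if (i, j) in self.C:
                    best = np.minimum(best, self.C[(i, j)])
                for k in range(i + 1, j - 3):
                    self.ops += 1
                    cand = self._mp(
                        self._mp(self.B[(i, k - 1)], E[k - 1]), self.C[(k, j)]
                    )
                    best = np.minimum(best, cand)
                self.B[(i, j)] = best
        return float(np.min(self.B[(0, self.L - 1)]))

    # .. nearest neighbor ..

    def _c_turner(self, i: int, j: int) -> np.ndarray:
        m, mu, E = self.model, self.mu, self.E
        pt = self.pt(i, j)
        aum = self.au(i, j)
        valid = pt >= 0
        po = np.where(valid, pt, 0)

        # hairpin
        best = mu * (m.hairpin(j - i - 1) + aum) + self.P[(i, j)]

        # stack on (i+1, j-1)
        if j - i >= 6:
            ptin = self.pt(i + 1, j - 1)
            cin = self.C.get((i + 1, j - 1))
            if cin is not None:
                rin = np.where(ptin >= 0, _REV[np.where(ptin >= 0, ptin, 0)], 0)
                X = (
                    E[i][:, :, None, None]
                    + cin[None, :, :, None]
                    + E[j - 1][None, None, :, :]
                )
                sterm = self.SY[po[:, None, None, :], rin[None, :, :, None]]
                cand = np.min(X + mu * sterm, axis=(1, 2))
                best = np.minimum(best, cand)

        # bulge / internal loops
        for p in range(i + 1, min(i + MAXLOOP + 1, j - 5) + 1):
            l1 = p - i - 1
            q_lo = max(p + 4, j - 1 - (MAXLOOP - l1))
            for q in range(q_lo, j):
                l2 = j - q - 1
                if l1 == 0 and l2 == 0:
                    continue
                cin = self.C.get((p, q))
                if cin is None:
                    continue
                self.ops += 1
                Lm, Rm = self.P[(i, p)], self.P[(q, j)]
                size = l1 + l2
                if size == 1:
                    ptin = self.pt(p, q)
                    rin = np.where(ptin >= 0, _REV[np.where(ptin >= 0, ptin, 0)], 0)
                    X = (
                        Lm[:, :, None, None]
                        + cin[None, :, :, None]
                        + Rm[None, None, :, :]
                    )
                    sterm = self.SY[po[:, None, None, :], rin[None, :, :, None]]
                    cand = np.min(X + mu * (sterm + m.bulge(1)), axis=(1, 2))
                else:
                    init = m.bulge(size) if (l1 == 0 or l2 == 0) else m.internal(size)
                    inner = cin + mu * (init + self.au(p, q))
                    cand = self._mp(self._mp(Lm, inner), Rm) + mu * aum
                best = np.minimum(best, cand)

        # multiloop: a + b*(branches incl. closing) + c*unpaired
        if j - i >= 11:
            acc = None
            for k in range(i + 5, j - 5):
                mseg = self.M.get((i + 1, k))
                m1seg = self.M1.get((k + 1, j - 1))
                if mseg is None or m1seg is None:
                    continue
                self.ops += 1
                cand = self._mp(self._mp(mseg, E[k]), m1seg)
                acc = cand if acc is None else np.minimum(acc, cand)
            if acc is not None:
                cand = (
                    mu * (m.ml_a + m.ml_b)
                    + mu * aum
                    + self._mp(self._mp(E[i], acc), E[j - 1])
                )
                best = np.minimum(best, cand)

        return np.where(valid, best, INF)

    def _forward_turner(self) -> float:
        m, mu, E = self.model, self.mu, self.E
        for j in range(self.L):
            for i in range(j - 4, -1, -1):
                self.C[(i, j)] = self._c_turner(i, j)
            self._prune_column(self.C, j)

            for i in range(j - 4, -1, -1):
                cand = self.C[(i, j)] + mu * (m.ml_b + self.au(i, j))
                prev = self.M1.get((i, j - 1))
                if prev is not None:
                    cand = np.minimum(cand, self._mp(prev, E[j - 1]) + mu * m.ml_c)
                self.M1[(i, j)] = cand
            self._prune_column(self.M1, j)

            for i in range(j - 4, -1, -1):
                best = self.M1[(i, j)].copy()
                lead = self.M.get((i + 1, j))
                if lead is not None:
                    best = np.minimum(best, self._mp(E[i], lead) + mu * m.ml_c)
                for k in range(i + 4, j - 4):
                    self.ops += 1
                    cand = self._mp(
                        self._mp(self.M[(i, k)], E[k]), self.M1[(k + 1, j)]
                    )
                    best = np.minimum(best, cand)
                self.M[(i, j)] = best

            # external loop
            if j == 0:
                self.F.append(np.zeros(self.n[0]))
                continue
            fj = np.min(self.F[j - 1][:, None] + E[j - 1], axis=0)
            for k in range(0, j - 3):
                self.ops += 1
                branch = self.C[(k, j)] + mu * self.au(k, j)
                if k == 0:
                    cand = np.min(branch, axis=0)
                else:
                    pre = np.min(self.F[k - 1][:, None] + E[k - 1], axis=0)
                    cand = np.min(pre[:, None] + branch, axis=0)
                fj = np.minimum(fj, cand)
            self.F.append(fj)
        return float(np.min(self.F[self.L - 1]))

    # -- traceback ----------------------------------------------------------

    def _traceback(self):
        self.assign: list[int | None] = [None] * self.L
        self.pairs: list[tuple[int, int]] = []
        if self.model.name == "nussinov":
            u, v = np.unravel_index(
                np.argmin(self.B[(0, self.L - 1)]), self.B[(0, self.L - 1)].shape
            )
            self._t_B(0, self.L - 1, int(u), int(v))
        else:
            v = int(np.argmin(self.F[self.L - 1]))
            self._t_F(self.L - 1, v)
        assert all(a is not None for a in self.assign)
        return self.assign, sorted(self.pairs)

    def _walk_path(self, i: int, j: int, u: int, v: int) -> None:
        """Assign the cheapest unpaired walk between fixed endpoints i, j."""
        self.assign[i] = u
        self.assign[j] = v
        cur = u
        for t in range(i + 1, j):
            col = self.E[t - 1][cur, :] + self.P[(t, j)][:, v]
            cur = int(np.argmin(col))
            self.assign[t] = cur

    # .. nussinov traceback ..

    def _t_B(self, i: int, j: int, u: int, v: int) -> None:
        while True:
            if i == j:
                self.assign[i] = u
                return
            # j unpaired
            col = self.B[(i, j - 1)][u, :] + self.E[j - 1][:, v]
            v2 = int(np.argmin(col))
            best, action = col[v2], ("unpaired", v2)
            if (i, j) in self.C and self.C[(i, j)][u, v] < best:
                best, action = self.C[(i, j)][u, v], ("pair_i",)
            for k in range(i + 1, j - 3):
                if (k, j) not in self.C:
                    continue
                X = (
                    self.B[(i, k - 1)][u, :][:, None]
                    + self.E[k - 1]
                    + self.C[(k, j)][:, v][None, :]
                )
                mm = np.unravel_index(np.argmin(X), X.shape)
                if X[mm] < best:
                    best, action = X[mm], ("split", k, int(mm[0]), int(mm[1]))
            if action[0] == "unpaired":
                self.assign[j] = v
                j, v = j - 1, action[1]
                continue
            if action[0] == "pair_i":
                self._t_C_nuss(i, j, u, v)
                return
            _, k, mth, m2 = action
            self._t_C_nuss(k, j, m2, v)
            j, v = k - 1, mth
            # continue tracing B[i, k-1]

    def _t_C_nuss(self, i: int, j: int, u: int, v: int) -> None:
        self.pairs.append((i, j))
        self.assign[i], self.assign[j] = u, v
        X = (
            self.E[i][u, :][:, None]
            + self.B[(i + 1, j - 1)]
            + self.E[j - 1][:, v][None, :]
        )
        u2, v2 = np.unravel_index(np.argmin(X), X.shape)
        self._t_B(i + 1, j - 1, int(u2), int(v2))

    # .. turner traceback ..

    def _t_F(self, j: int, v: int) -> None:
        mu = self.mu
        while True:
            if j == 0:
                self.assign[0] = v
                return
            col = self.F[j - 1] + self.E[j - 1][:, v]
            v2 = int(np.argmin(col))
            best, action = col[v2], ("unpaired", v2)
            for k in range(0, j - 3):
                branch = self.C[(k, j)][:, v] + mu * self.au(k, j)[:, v]
                if k == 0:
                    u = int(np.argmin(branch))
                    val, act = branch[u], ("branch0", u)
                else:
                    pre = self.F[k - 1][:, None] + self.E[k - 1]
                    X = np.min(pre, axis=0) + branch
                    u = int(np.argmin(X))
                    mth = int(np.argmin(pre[:, u]))
                    val, act = X[u], ("branch", k, u, mth)
                if val < best:
                    best, action = val, act
            if action[0] == "unpaired":
                self.assign[j] = v
                j, v = j - 1, action[1]
                continue
            if action[0] == "branch0":
                self._t_C(0, j, action[1], v)
                return
            _, k, u, mth = action
            self._t_C(k, j, u, v)
            j, v = k - 1, mth

    def _t_C(self, i: int, j: int, u: int, v: int) -> None:
        m, mu, E = self.model, self.mu, self.E
        self.pairs.append((i, j))
        po = self.pt(i, j)[u, v]
        au_uv = self.au(i, j)[u, v]

        best = mu * (m.hairpin(j - i - 1) + au_uv) + self.P[(i, j)][u, v]
        action: tuple = ("hairpin",)

        if j - i >= 6 and (i + 1, j - 1) in self.C:
            ptin = self.pt(i + 1, j - 1)
            rin = np.where(ptin >= 0, _REV[np.where(ptin >= 0, ptin, 0)], 0)
            X = (
                E[i][u, :][:, None]
                + self.C[(i + 1, j - 1)]
                + E[j - 1][:, v][None, :]
                + mu * self.SY[po, rin]
            )
            mm = np.unravel_index(np.argmin(X), X.shape)
            if X[mm] < best:
                best, action = X[mm], ("stack", int(mm[0]), int(mm[1]))

        for p in range(i + 1, min(i + MAXLOOP + 1, j - 5) + 1):
            l1 = p - i - 1
            for q in range(max(p + 4, j - 1 - (MAXLOOP - l1)), j):
                l2 = j - q - 1
                if (l1 == 0 and l2 == 0) or (p, q) not in self.C:
                    continue
                Lr = self.P[(i, p)][u, :]
                Rr = self.P[(q, j)][:, v]
                size = l1 + l2
                if size == 1:
                    ptin = self.pt(p, q)
                    rin = np.where(ptin >= 0, _REV[np.where(ptin >= 0, ptin, 0)], 0)
                    X = (
                        Lr[:, None]
                        + self.C[(p, q)]
                        + Rr[None, :]
                        + mu * (self.SY[po, rin] + m.bulge(1))
                    )
                else:
                    init = m.bulge(size) if (l1 == 0 or l2 == 0) else m.internal(size)
                    X = (
                        Lr[:, None]
                        + self.C[(p, q)]
                        + mu * (init + self.au(p, q))
                        + Rr[None, :]
                        + mu * au_uv
                    )
                mm = np.unravel_index(np.argmin(X), X.shape)
                if X[mm] < best:
                    best, action = X[mm], ("loop", p, q, int(mm[0]), int(mm[1]))

        if j - i >= 11:
            for k in range(i + 5, j - 5):
                mseg = self.M.get((i + 1, k))
                m1seg = self.M1.get((k + 1, j - 1))
                if mseg is None or m1seg is None:
                    continue
                X = (
                    E[i][u, :][:, None, None, None]
                    + mseg[:, :, None, None]
                    + E[k][None, :, :, None]
                    + m1seg[None, None, :, :]
                )
                X = X + E[j - 1][:, v][None, None, None, :]
                X = X + mu * (m.ml_a + m.ml_b + au_uv)
                mm = np.unravel_index(np.argmin(X), X.shape)
                if X[mm] < best:
                    best, action = X[mm], (
                        "ml", k, int(mm[0]), int(mm[1]), int(mm[2]), int(mm[3])
                    )

        self.assign[i], self.assign[j] = u, v
        if action[0] == "hairpin":
            self._walk_path(i, j, u, v)
        elif action[0] == "stack":
            _, u2, v2 = action
            self._t_C(i + 1, j - 1, u2, v2)
        elif action[0] == "loop":
            _, p, q, mth, nth = action
            self._walk_path(i, p, u, mth)
            self._walk_path(q, j, nth, v)
            self._t_C(p, q, mth, nth)
        else:
            _, k, u2, mth, m2, v2 = action
            self._t_M(i + 1, k, u2, mth)
            self._t_M1(k + 1, j - 1, m2, v2)

    def _t_M(self, i: int, j: int, u: int, v: int) -> None:
        m, mu, E = self.model, self.mu, self.E
        while True:
            best, action = self.M1[(i, j)][u, v], ("m1",)
            lead = self.M.get((i + 1, j))
            if lead is not None:
                col = E[i][u, :] + lead[:, v] + mu * m.ml_c
                u2 = int(np.argmin(col))
                if col[u2] < best:
                    best, action = col[u2], ("lead", u2)
            for k in range(i + 4, j - 4):
                X = (
                    self.M[(i, k)][u, :][:, None]
                    + E[k]
                    + self.M1[(k + 1, j)][:, v][None, :]
                )
                mm = np.unravel_index(np.argmin(X), X.shape)
                if X[mm] < best:
                    best, action = X[mm], ("split", k, int(mm[0]), int(mm[1]))
            if action[0] == "m1":
                self._t_M1(i, j, u, v)
                return
            if action[0] == "lead":
                self.assign[i] = u
                i, u = i + 1, action[1]
                continue
            _, k, mth, m2 = action
            self._t_M1(k + 1, j, m2, v)
            j, v = k, mth
            # continue tracing M[i, k]

    def _t_M1(self, i: int, j: int, u: int, v: int) -> None:
        m, mu, E = self.model, self.mu, self.E
        while True:
            best = self.C[(i, j)][u, v] + mu * (m.ml_b + self.au(i, j)[u, v])
            action: tuple = ("branch",)
            prev = self.M1.get((i, j - 1))
            if prev is not None:
                col = prev[u, :] + E[j - 1][:, v] + mu * m.ml_c
                v2 = int(np.argmin(col))
                if col[v2] < best:
                    best, action = col[v2], ("unpaired", v2)
            if action[0] == "branch":
                self._t_C(i, j, u, v)
                return
            self.assign[j] = v
            j, v = j - 1, action[1]


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------


def design(
    lattice: CodonLattice,
    model: EnergyModel,
    objective: Objective,
    beam: int | None = None,
) -> DesignResult:
    """Design the CDS + structure minimizing the scalarized objective.

    With ``beam=None`` the search is exact: the result attains the global
    minimum of ``mu*E - kappa*S`` over every (synonymous CDS, structure)
    pair.  With a finite beam only the ``beam`` best entries of the pairing
    matrices are kept per right endpoint, so the result is feasible but its
    objective may exceed the exact optimum.
    """
    folder = _LatticeFolder(lattice, model, objective.mu, objective.kappa, beam)
    value, assign, pairs = folder.solve()
    cds = "".join(folder.nucs[i][assign[i]] for i in range(folder.L))
    structure = _pairs_to_db(folder.L, pairs)

    S = -sum(
        lattice.states[i][assign[i]].neg_log_w for i in range(2, folder.L, 3)
    )
    mfe = score_structure(cds, structure, model)
    obj = objective.value(mfe, S)
    if beam is None and not math.isclose(obj, value, rel_tol=0, abs_tol=1e-6):
        raise RuntimeError(
            f"DP/objective mismatch: DP={value!r} rescored={obj!r} "
            f"(cds={cds}, structure={structure})"
        )
    n_codons = folder.L // 3
    return DesignResult(
        cds=cds,
        structure=structure,
        mfe=mfe,
        S=S,
        cai=math.exp(S / n_codons),
        objective_value=obj,
        lambda_used=objective.lam,
        formulation=objective.formulation,
        exact=beam is None,
    )


def _pairs_to_db(L: int, pairs: list[tuple[int, int]]) -> str:
    chars = ["."] * L
    for i, j in pairs:
        chars[i], chars[j] = "(", ")"
    return "".join(chars)


def _fixed_lattice(seq: str) -> CodonLattice:
    """Degenerate one-state-per-position lattice spelling exactly ``seq``."""
    states: list[list[LatticeState]] = []
    for i in range(len(seq)):
        start = (i // 3) * 3
        prefix = seq[start : i + 1]
        codon = prefix if (i % 3 == 2) else None
        states.append([LatticeState(i, prefix, codon=codon, neg_log_w=0.0)])
    lat = CodonLattice.__new__(CodonLattice)
    lat.protein = None
    lat.states = states
    lat.length = len(states)
    return lat


def fold_fixed(seq: str, model: EnergyModel) -> tuple[float, str]:
    """Minimum free energy fold of a fixed RNA sequence.

    Runs the lattice DP on the degenerate single-path lattice with
    ``kappa=0``; returns ``(mfe, dot_bracket)`` with the reported energy
    guaranteed to equal ``score_structure`` of the returned structure.
    """
    seq = seq.upper().replace("T", "U")
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotides {sorted(bad)} in sequence")
    folder = _LatticeFolder(_fixed_lattice(seq), model, mu=1.0, kappa=0.0)
    value, _assign, pairs = folder.solve()
    structure = _pairs_to_db(len(seq), pairs)
    mfe = score_structure(seq, structure, model)
    if not math.isclose(mfe, value, rel_tol=0, abs_tol=1e-6):
        raise RuntimeError(
            f"fold/score mismatch: DP={value!r} rescored={mfe!r} ({seq} {structure})"
        )
    return mfe, structure


def fold_energy(seq: str, model: EnergyModel) -> float:
    """Forward-only MFE (no traceback); used by the brute-force oracle."""
    seq = seq.upper().replace("T", "U")
    folder = _LatticeFolder(_fixed_lattice(seq), model, mu=1.0, kappa=0.0)
    value, _, _ = folder.solve(trace=False)
    return value
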