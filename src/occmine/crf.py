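"""Linear-chain conditional random field for sequence labelling.

A first-order CRF over string-valued features with L2 regularization,
trained by L-BFGS on the exact negative log-likelihood (forward-backward
gradients) and decoded with Viterbi.  The model is deliberately small and
deterministic: the feature vocabulary is frozen in first-seen order over the
training sequences, the optimizer is derivative-based with a fixed iteration
cap, and decoding breaks score ties by label index.

The joint score of a label sequence y for a T-token sequence is

    s(y) = b_start[y_1] + sum_t  w(f_t) . y_t
                        + sum_t  A[y_{t-1}, y_t] + b_end[y_T]

with per-token emission weights ``w`` indexed by the token's active feature
strings and a dense label-transition matrix ``A``.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.optimize import minimize
from scipy.special import logsumexp

FeatureSeq = list[list[str]]  # one list of feature strings per token


class LinearChainCRF:
    """L2-regularized linear-chain CRF.

    Parameters
    ----------
    c2:
        L2 penalty weight on all parameters (default 0.1).
    max_iterations:
        L-BFGS iteration cap (default 100).
    """

    def __init__(self, c2: float = 0.1, max_iterations: int = 100):
        self.c2 = float(c2)
        self.max_iterations = int(max_iterations)
        self.labels_: list[str] | None = None
        self.feature_index_: dict[str, int] | None = None
        self.W_: np.ndarray | None = None       # (F, L) emissions
        self.A_: np.ndarray | None = None       # (L, L) transitions
        self.b_start_: np.ndarray | None = None
        self.b_end_: np.ndarray | None = None

    # ------------------------------------------------------------------ fit

    def fit(self, X: list[FeatureSeq], y: list[list[str]],
            labels: list[str] | None = None) -> "LinearChainCRF":
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        pairs = [(xs, ys) for xs, ys in zip(X, y) if len(xs)]
        if not pairs:
            raise ValueError("no non-empty training sequences")
        for xs, ys in pairs:
            if len(xs) != len(ys):
                raise ValueError("sequence/label length mismatch")

        if labels is None:
            seen: dict[str, None] = {}
            for _, ys in pairs:
                for lab in ys:
                    seen.setdefault(lab)
            labels = list(seen)
        self.labels_ = list(labels)
        lab_idx = {lab: i for i, lab in enumerate(self.labels_)}
        L = len(self.labels_)

        feat_idx: dict[str, int] = {}
        for xs, _ in pairs:
            for feats in xs:
                for f in feats:
                    feat_idx.setdefault(f, len(feat_idx))
        self.feature_index_ = feat_idx
        F = len(feat_idx)

        # one big sparse design matrix over all tokens, plus sequence offsets
        rows, cols = [], []
        bounds = [0]
        gold: list[int] = []
        for xs, ys in pairs:
            for feats, lab in zip(xs, ys):
                r = len(gold)
                gold.append(lab_idx[lab])
                for f in feats:
                    rows.append(r)
                    cols.append(feat_idx[f])
            bounds.append(len(gold))
        N = len(gold)
        Xmat = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(N, F))
        gold_arr = np.asarray(gold)
        Y_onehot = np.zeros((N, L))
        Y_onehot[np.arange(N), gold_arr] = 1.0

        nW = F * L
        nA = L * L

        def unpack(theta):
            W = theta[:nW].reshape(F, L)
            A = theta[nW:nW + nA].reshape(L, L)
            bs = theta[nW + nA:nW + nA + L]
            be = theta[nW + nA + L:]
            return W, A, bs, be

        def objective(theta):
            W, A, bs, be = unpack(theta)
            E = Xmat @ W  # (N, L) emission scores
            gE = np.zeros_like(E)
            gA = np.zeros_like(A)
            gbs = np.zeros(L)
            gbe = np.zeros(L)
            nll = 0.0
            for k in range(len(bounds) - 1):
                s, e = bounds[k], bounds[k + 1]
                n = e - s
                Ek = E[s:e]
                yk = gold_arr[s:e]
                # forward
                alpha = np.empty((n, L))
                alpha[0] = bs + Ek[0]
                for t in range(1, n):
                    alpha[t] = Ek[t] + logsumexp(
                        alpha[t - 1][:, None] + A, axis=0)
                logZ = logsumexp(alpha[-1] + be)
                # backward
                beta = np.empty((n, L))
                beta[-1] = be
                for t in range(n - 2, -1, -1):
                    beta[t] = logsumexp(
                        A + (Ek[t + 1] + beta[t + 1])[None, :], axis=1)
                post = np.exp(alpha + beta - logZ)  # (n, L) marginals
                gE[s:e] = post
                gbs += post[0]
                gbe += post[-1]
                for t in range(1, n):
                    pair = np.exp(
                        alpha[t - 1][:, None] + A
                        + (Ek[t] + beta[t])[None, :] - logZ)
                    gA += pair
                    gA[yk[t - 1], yk[t]] -= 1.0
                # gold score
                score = bs[yk[0]] + Ek[np.arange(n), yk].sum() + be[yk[-1]]
                if n > 1:
                    score += A[yk[:-1], yk[1:]].sum()
                nll += logZ - score
            gE -= Y_onehot
            gbs -= Y_onehot[np.asarray(bounds[:-1])].sum(axis=0)
            gbe -= Y_onehot[np.asarray(bounds[1:]) - 1].sum(axis=0)
            gW = (Xmat.T @ gE)
            grad = np.concatenate(
                [np.asarray(gW).ravel(), gA.ravel(), gbs, gbe])
            nll += 0.5 * self.c2 * float(theta @ theta)
            grad += self.c2 * theta
            return nll, grad

        theta0 = np.zeros(nW + nA + 2 * L)
        res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                       options={"maxiter": self.max_iterations})
        self.W_, self.A_, self.b_start_, self.b_end_ = unpack(res.x)
        return self

    # -------------------------------------------------------------- predict

    def _emissions(self, xs: FeatureSeq) -> np.ndarray:
        assert self.feature_index_ is not None and self.W_ is not None
        E = np.zeros((len(xs), self.W_.shape[1]))
        for t, feats in enumerate(xs):
            for f in feats:
                j = self.feature_index_.get(f)
                if j is not None:
                    E[t] += self.W_[j]
        return E

    def predict_single(self, xs: FeatureSeq) -> list[str]:
        """Viterbi decoding; ties broken toward the lower label index."""
        if self.labels_ is None:
            raise RuntimeError("model is not fitted")
        if not xs:
            return []
        L = len(self.labels_)
        E = self._emissions(xs)
        n = len(xs)
        delta = np.empty((n, L))
        back = np.zeros((n, L), dtype=int)
        delta[0] = self.b_start_ + E[0]
        for t in range(1, n):
            cand = delta[t - 1][:, None] + self.A_
            back[t] = np.argmax(cand, axis=0)
            delta[t] = E[t] + cand[back[t], np.arange(L)]
        delta[-1] += self.b_end_
        path = np.empty(n, dtype=int)
        path[-1] = int(np.argmax(delta[-1]))
        for t in range(n - 1, 0, -1):
            path[t - 1] = back[t, path[t]]
        return [self.labels_[i] for i in path]

    def predict(self, X: list[FeatureSeq]) -> list[list[str]]:
        return [self.predict_single(xs) for xs in X]

    # ------------------------------------------------------------- scoring

    def sequence_score(self, xs: FeatureSeq, ys: list[str]) -> float:
        """Unnormalized joint score of a label sequence."""
        if self.labels_ is None:
            raise RuntimeError("model is not fitted")
        idx = [self.labels_.index(y) for y in ys]
        E = self._emissions(xs)
        score = self.b_start_[idx[0]] + self.b_end_[idx[-1]]
        score += sum(E[t, i] for t, i in enumerate(idx))
        score += sum(self.A_[idx[t - 1], idx[t]] for t in range(1, len(idx)))
        return float(score)

    def log_partition(self, xs: FeatureSeq) -> float:
        """log Z, the log-sum-exp of sequence scores over all labelings."""
        if self.labels_ is None:
            raise RuntimeError("model is not fitted")
        E = self._emissions(xs)
        alpha = self.b_start_ + E[0]
        for t in range(1, len(xs)):
            alpha = E[t] + logsumexp(alpha[:, None] + self.A_, axis=0)
        return float(logsumexp(alpha + self.b_end_))
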