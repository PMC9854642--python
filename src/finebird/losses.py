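"""Classification and distillation losses.

The teacher is trained with plain cross-entropy on three image branches
(raw, object crop, key-part crops); the student is trained with
cross-entropy plus a decoupled knowledge-distillation (DKD) term against
the frozen teacher.

Classical logit distillation is the temperature-softened KL divergence
KL(P^T || P^S).  It factors exactly into a target/non-target binary term
(TCKD) and a renormalized non-target term (NCKD):

    KD = TCKD + (1 - p_t^T) * NCKD

so a confident teacher (p_t^T near 1) suppresses the non-target knowledge.
DKD replaces the coupled weight with a free hyperparameter:

    DKD = TCKD + alpha * NCKD        (default alpha = 2)

All probability computations here apply the same temperature T so the
factorization above holds identically at any T; everything is evaluated in
log space with float64 so the identity is exact to ~1e-12.

Functions accept a single logit vector (C,) or a batch (N, C); losses come
back as a scalar or a length-N array correspondingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "DKDBreakdown",
    "TeacherLossBundle",
    "StudentLossBundle",
    "softmax_t",
    "cross_entropy",
    "cross_entropy_from_logits",
    "teacher_total_loss",
    "kd_loss",
    "binary_split",
    "nontarget_probs",
    "tckd",
    "nckd",
    "dkd_loss",
    "dkd_components",
    "student_total_loss",
    "ce_grad_from_logits",
    "kd_grad",
    "dkd_grad",
]

_EPS = 1e-12


@dataclass(frozen=True)
class DKDBreakdown:
    """Per-pair decomposition of the decoupled distillation loss."""

    tckd: float
    nckd: float
    teacher_pt: float
    alpha: float
    total: float


@dataclass(frozen=True)
class TeacherLossBundle:
    """Raw / object / part cross-entropy losses and their sum."""

    l_r: float
    l_o: float
    l_p: float
    l_total: float


@dataclass(frozen=True)
class StudentLossBundle:
    """Hard (cross-entropy) and soft (DKD) losses and their sum."""

    l_hard: float
    l_soft: float
    l_total: float


def _check_temperature(T: float) -> None:
    if not T > 0:
        raise ValueError(f"temperature must be > 0, got {T}")


def _log_softmax(z: np.ndarray, T: float) -> np.ndarray:
    s = np.asarray(z, dtype=np.float64) / T
    return s - logsumexp(s, axis=-1, keepdims=True)


def softmax_t(z: np.ndarray, T: float = 1.0) -> np.ndarray:
    """Temperature-softened softmax p_i = exp(z_i/T) / sum_j exp(z_j/T).

    Computed with max subtraction (via log-sum-exp), so huge logits do not
    overflow.
    """
    _check_temperature(T)
    return np.exp(_log_softmax(z, T))


def cross_entropy(p: np.ndarray, label) -> float | np.ndarray:
    """-log p_label, with p clamped at 1e-12 inside the log."""
    p = np.asarray(p, dtype=np.float64)
    label = np.asarray(label)
    if np.any(label < 0) or np.any(label >= p.shape[-1]):
        raise IndexError(f"label out of range for {p.shape[-1]} classes")
    p_label = np.take_along_axis(p, label[..., None], axis=-1)[..., 0]
    out = -np.log(np.maximum(p_label, _EPS))
    return float(out) if out.ndim == 0 else out


def cross_entropy_from_logits(z: np.ndarray, label, T: float = 1.0):
    """Cross-entropy evaluated directly from logits (numerically exact)."""
    _check_temperature(T)
    lsm = _log_softmax(z, T)
    label = np.asarray(label)
    out = -np.take_along_axis(lsm, label[..., None], axis=-1)[..., 0]
    return float(out) if out.ndim == 0 else out


def teacher_total_loss(p_raw, p_obj, p_parts, label) -> TeacherLossBundle:
    """Three-branch teacher loss: L_total = L_r + L_o + L_p.

    ``p_parts`` is a (possibly empty) list of probability vectors, one per
    key-part crop; L_p sums their cross-entropies.
    """
    p_raw = np.asarray(p_raw, dtype=np.float64)
    C = p_raw.shape[-1]
    for p in [p_obj, *p_parts]:
        if np.asarray(p).shape[-1] != C:
            raise ValueError("mismatched class counts across branches")
    l_r = float(np.mean(cross_entropy(p_raw, label)))
    l_o = float(np.mean(cross_entropy(np.asarray(p_obj), label)))
    l_p = float(sum(np.mean(cross_entropy(np.asarray(p), label)) for p in p_parts))
    return TeacherLossBundle(l_r, l_o, l_p, l_r + l_o + l_p)


def kd_loss(z_teacher, z_student, T: float = 4.0):
    """Classical logit distillation KL(P^T || P^S) at temperature T."""
    _check_temperature(T)
    lt = _log_softmax(z_teacher, T)
    ls = _log_softmax(z_student, T)
    out = np.sum(np.exp(lt) * (lt - ls), axis=-1)
    return float(out) if out.ndim == 0 else out


def _binary_logprobs(z, target, T: float):
    """(log p_t, log p_not_t) of the target/rest split, in log space."""
    lsm = _log_softmax(z, T)
    target = np.asarray(target)
    lpt = np.take_along_axis(lsm, target[..., None], axis=-1)[..., 0]
    masked = lsm.copy()
    np.put_along_axis(masked, target[..., None], -np.inf, axis=-1)
    lpnt = logsumexp(masked, axis=-1)
    return lpt, lpnt


def binary_split(z, target, T: float = 4.0) -> tuple:
    """Probabilities (p_t, p_not_t) of the target class and of everything else."""
    _check_temperature(T)
    lpt, lpnt = _binary_logprobs(z, target, T)
    return np.exp(lpt), np.exp(lpnt)


def _nontarget_log_softmax(z, target, T: float) -> np.ndarray:
    """Log-softmax over the non-target logits; -inf in the target slot."""
    s = np.asarray(z, dtype=np.float64) / T
    masked = s.copy()
    np.put_along_axis(masked, np.asarray(target)[..., None], -np.inf, axis=-1)
    return masked - logsumexp(masked, axis=-1, keepdims=True)


def nontarget_probs(z, target: int, T: float = 4.0) -> np.ndarray:
    """Softmax over the C-1 non-target logits (target excluded entirely).

    Invariant to the target logit's value.  Single-vector API: returns a
    length-(C-1) array.
    """
    _check_temperature(T)
    z = np.asarray(z, dtype=np.float64)
    if z.ndim != 1:
        raise ValueError("nontarget_probs takes a single logit vector")
    if z.shape[0] < 2:
        raise ValueError("need at least 2 classes")
    lns = _nontarget_log_softmax(z, np.asarray(target), T)
    keep = np.arange(z.shape[0]) != target
    return np.exp(lns[keep])


def tckd(z_teacher, z_student, target, T: float = 4.0):
    """Target-class term: KL between the 2-element (target, rest) splits."""
    _check_temperature(T)
    lpt_t, lpnt_t = _binary_logprobs(z_teacher, target, T)
    lpt_s, lpnt_s = _binary_logprobs(z_student, target, T)
    out = np.exp(lpt_t) * (lpt_t - lpt_s) + np.exp(lpnt_t) * (lpnt_t - lpnt_s)
    out = np.maximum(out, 0.0)  # KL; guards -0.0 from rounding
    return float(out) if out.ndim == 0 else out


def nckd(z_teacher, z_student, target, T: float = 4.0):
    """Non-target term: KL between the renormalized non-target distributions.

    Identically 0 for C = 2 (both distributions are the singleton [1])."""
    _check_temperature(T)
    target = np.asarray(target)
    lt = _nontarget_log_softmax(z_teacher, target, T)
    ls = _nontarget_log_softmax(z_student, target, T)
    # neutralize the target slot (-inf in both) so it contributes exactly 0
    np.put_along_axis(lt, target[..., None], 0.0, axis=-1)
    np.put_along_axis(ls, target[..., None], 0.0, axis=-1)
    out = np.sum(np.exp(lt) * (lt - ls), axis=-1)
    out = np.maximum(out, 0.0)
    return float(out) if out.ndim == 0 else out


def dkd_components(z_teacher, z_student, target, T: float = 4.0):
    """(tckd, nckd, teacher p_t) as arrays, shared softmax work."""
    t_val = tckd(z_teacher, z_student, target, T)
    n_val = nckd(z_teacher, z_student, target, T)
    lpt_t, _ = _binary_logprobs(z_teacher, target, T)
    return t_val, n_val, np.exp(lpt_t)


def dkd_loss(z_teacher, z_student, target, T: float = 4.0, alpha: float = 2.0) -> DKDBreakdown:
    """Decoupled distillation DKD = TCKD + alpha * NCKD for one logit pair."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    t_val, n_val, pt = dkd_components(z_teacher, z_student, target, T)
    t_val = float(np.mean(t_val))
    n_val = float(np.mean(n_val))
    return DKDBreakdown(t_val, n_val, float(np.mean(pt)), alpha, t_val + alpha * n_val)


def student_total_loss(streams, T: float = 4.0, alpha: float = 2.0) -> StudentLossBundle:
    """Student objective over training streams: L_total = L_hard + L_soft.

    ``streams`` is a non-empty list of (z_student, z_teacher, label) tuples,
    one per image stream (raw plus the object/part crops from both models'
    attention).  The hard loss is plain cross-entropy at T=1, the soft loss
    the DKD value at temperature T; both are summed over streams.
    """
    if not streams:
        raise ValueError("need at least one stream")
    l_hard = 0.0
    l_soft = 0.0
    for z_s, z_t, label in streams:
        l_hard += float(np.mean(cross_entropy_from_logits(z_s, np.asarray(label), 1.0)))
        l_soft += dkd_loss(z_t, z_s, np.asarray(label), T, alpha).total
    return StudentLossBundle(l_hard, l_soft, l_hard + l_soft)


# ---------------------------------------------------------------------------
# analytic gradients w.r.t. student logits (for the numpy training loops)


def _onehot_like(z: np.ndarray, label: np.ndarray) -> np.ndarray:
    oh = np.zeros_like(z)
    np.put_along_axis(oh, label[..., None], 1.0, axis=-1)
    return oh


def ce_grad_from_logits(z, label) -> np.ndarray:
    """d CE(softmax(z), label) / dz = softmax(z) - onehot(label)."""
    z = np.asarray(z, dtype=np.float64)
    return softmax_t(z, 1.0) - _onehot_like(z, np.asarray(label))


def kd_grad(z_teacher, z_student, T: float = 4.0) -> np.ndarray:
    """d KL(P^T || P^S) / dz_student = (P^S - P^T) / T."""
    return (softmax_t(z_student, T) - softmax_t(z_teacher, T)) / T


def dkd_grad(z_teacher, z_student, target, T: float = 4.0, alpha: float = 2.0) -> np.ndarray:
    """Gradient of TCKD + alpha*NCKD w.r.t. the student logits."""
    target = np.asarray(target)
    z_s = np.asarray(z_student, dtype=np.float64)
    p_s = softmax_t(z_s, T)
    pt_s = np.take_along_axis(p_s, target[..., None], axis=-1)[..., 0]
    a, _ = binary_split(z_teacher, target, T)  # teacher p_t
    # TCKD: d/ds_j = c * (1[j=t] - p_j), c = (1-a) pt/(1-pt) - a
    coef = (1.0 - a) * pt_s / np.maximum(1.0 - pt_s, _EPS) - a
    g_tckd = coef[..., None] * (_onehot_like(z_s, target) - p_s)
    # NCKD: cross-entropy grad over the non-target softmax, 0 in the target slot
    phat_s = np.exp(_nontarget_log_softmax(z_s, target, T))
    phat_t = np.exp(_nontarget_log_softmax(np.asarray(z_teacher, np.float64), target, T))
    g_nckd = phat_s - phat_t
    np.put_along_axis(g_nckd, target[..., None], 0.0, axis=-1)
    return (g_tckd + alpha * g_nckd) / T
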