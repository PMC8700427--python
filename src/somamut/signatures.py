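"""De-novo mutational-signature extraction and reference matching.

The per-sample 96-context count matrix V (96 x samples) is factorised as
V ~ W H with non-negative W (96 x k process profiles) and H (k x samples
exposures) by multiplicative-update NMF under the Kullback-Leibler
objective, the classical formulation for mutational-signature discovery.
Each candidate rank k is fitted from multiple random restarts; the restart
with the lowest reconstruction error is kept and a stability score (mean
pairwise cosine similarity of matched profile columns across restarts)
guides rank selection: the default chosen k is the smallest candidate whose
stability reaches the configured floor.

Extracted profiles are matched to the bundled reference catalogue by best
cosine similarity (greedy, per column; the assignment need not be injective
and duplicates are flagged), and each sample is labelled by the reference
index of its largest exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import NMF

from .spectra import CONTEXTS_96, SpectrumMatrix

log = logging.getLogger(__name__)

__all__ = [
    "SignatureSet",
    "SampleSignatureCall",
    "extract_signatures",
    "match_cosmic",
    "refit_exposures",
    "assign_samples",
    "cosine_similarity",
]


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = float(np.linalg.norm(a)), float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


@dataclass
class SampleSignatureCall:
    sample_id: str
    dominant_signature: int
    exposure_fraction: float


@dataclass
class SignatureSet:
    """Result of one extraction: factors, diagnostics and reference matches."""

    W: pd.DataFrame  # 96 x k, columns sum to 1
    H: pd.DataFrame  # k x samples
    k: int
    rank_diagnostics: pd.DataFrame  # per candidate k: error, stability
    cosmic_match: pd.DataFrame | None = None  # filled by match_cosmic

    def exposures(self) -> pd.DataFrame:
        """Per-sample exposure fractions (columns sum to 1)."""
        totals = self.H.sum(axis=0)
        return self.H.div(totals.where(totals > 0, 1.0), axis=1)


def _as_count_matrix(matrix: SpectrumMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(matrix, SpectrumMatrix):
        df = matrix.context_counts
    else:
        df = matrix
    if list(df.columns) != list(CONTEXTS_96):
        raise ValueError("context matrix must have the canonical 96 columns")
    return df


def _fit_once(V: np.ndarray, k: int, random_state: int, max_iter: int):
    model = NMF(
        n_components=k,
        init="random",
        solver="mu",
        beta_loss="kullback-leibler",
        max_iter=max_iter,
        random_state=random_state,
        tol=1e-6,
    )
    W = model.fit_transform(V)
    return W, model.components_, float(model.reconstruction_err_)


def _normalise(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scale = W.sum(axis=0)
    scale[scale == 0] = 1.0
    return W / scale, H * scale[:, None]


def _pairwise_stability(Ws: Sequence[np.ndarray]) -> float:
    """Mean cosine of optimally matched columns over all restart pairs."""
    sims = []
    for i in range(len(Ws)):
        for j in range(i + 1, len(Ws)):
            C = np.array([
                [cosine_similarity(Ws[i][:, a], Ws[j][:, b])
                 for b in range(Ws[j].shape[1])]
                for a in range(Ws[i].shape[1])
            ])
            rows, cols = linear_sum_assignment(-C)
            sims.append(float(C[rows, cols].mean()))
    return float(np.mean(sims)) if sims else 1.0


def extract_signatures(
    matrix: SpectrumMatrix | pd.DataFrame,
    k_range: int | Iterable[int] = (2, 3, 4),
    n_restarts: int = 10,
    seed: int = 0,
    stability_floor: float = 0.8,
    max_iter: int = 600,
) -> SignatureSet:
    """Best-of-restarts KL-NMF over candidate ranks; deterministic given seed.

    For the chosen k the lowest-error restart is returned with W columns
    normalised to unit sum (the compensating scale folded into H).
    """
    counts = _as_count_matrix(matrix)
    V = counts.to_numpy(dtype=float).T  # 96 x samples
    n_samples = V.shape[1]
    if n_samples < 2:
        raise ValueError("signature extraction needs at least 2 samples")
    if V.sum() == 0:
        raise ValueError("all-zero context matrix")

    ks = [k_range] if isinstance(k_range, int) else sorted(set(int(k) for k in k_range))
    if any(k < 1 or k > n_samples for k in ks):
        raise ValueError(f"rank out of range for {n_samples} samples: {ks}")

    rng = np.random.default_rng(seed)
    diagnostics = []
    best_by_k: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
    for k in ks:
        restarts = []
        for _ in range(max(1, n_restarts)):
            rs = int(rng.integers(0, 2**31 - 1))
            restarts.append(_fit_once(V, k, rs, max_iter))
        errors = [err for _, _, err in restarts]
        best = restarts[int(np.argmin(errors))]
        Ws = [_normalise(W, H)[0] for W, H, _ in restarts]
        stability = _pairwise_stability(Ws)
        diagnostics.append({"k": k, "reconstruction_error": min(errors),
                            "stability": stability})
        best_by_k[k] = best

    diag = pd.DataFrame(diagnostics).set_index("k")
    stable = [k for k in ks if diag.loc[k, "stability"] >= stability_floor]
    chosen = stable[0] if stable else int(diag["stability"].idxmax())
    if not stable:
        log.warning("no candidate rank reached stability %.2f; using k=%d "
                    "(most stable)", stability_floor, chosen)

    W, H, _ = best_by_k[chosen]
    W, H = _normalise(W, H)
    cols = [f"S{i + 1}" for i in range(chosen)]
    return SignatureSet(
        W=pd.DataFrame(W, index=list(CONTEXTS_96), columns=cols),
        H=pd.DataFrame(H, index=cols, columns=list(counts.index)),
        k=chosen,
        rank_diagnostics=diag,
    )


def refit_exposures(
    matrix: SpectrumMatrix | pd.DataFrame,
    reference: pd.DataFrame,
) -> pd.DataFrame:
    """Non-default attribution mode: refit each sample against the full
    reference catalogue by non-negative least squares.

    Returns a (reference signatures x samples) exposure matrix in mutation
    counts; no de-novo extraction is involved. Useful when the catalogue is
    trusted and per-sample attribution, not discovery, is the goal.
    """
    from scipy.optimize import nnls

    counts = _as_count_matrix(matrix)
    if list(reference.index) != list(CONTEXTS_96):
        raise ValueError("reference must carry the canonical 96-row labelling")
    A = reference.to_numpy(dtype=float)
    H = np.column_stack([
        nnls(A, counts.loc[s].to_numpy(dtype=float))[0] for s in counts.index
    ])
    return pd.DataFrame(H, index=list(reference.columns),
                        columns=list(counts.index))


def match_cosmic(
    W: pd.DataFrame,
    reference: pd.DataFrame,
    cosine_floor: float = 0.75,
) -> pd.DataFrame:
    """Best-cosine reference assignment for each extracted profile.

    ``reference`` columns are named like ``Signature.7``; the returned table
    has one row per extracted column with the matched reference index, the
    cosine similarity, a low-similarity flag (below ``cosine_floor``) and a
    duplicate flag when two extracted profiles hit the same reference.
    """
    if list(W.index) != list(reference.index):
        raise ValueError("extracted and reference matrices must share the "
                         "same 96-row labelling")
    ref = reference.to_numpy(dtype=float)
    ref_indices = [int(str(c).rsplit(".", 1)[-1]) for c in reference.columns]
    rows = []
    for col in W.columns:
        w = W[col].to_numpy(dtype=float)
        sims = np.array([cosine_similarity(w, ref[:, j]) for j in range(ref.shape[1])])
        j = int(np.argmax(sims))
        rows.append({"extracted": col, "matched_signature": ref_indices[j],
                     "cosine": float(sims[j]),
                     "low_similarity": bool(sims[j] < cosine_floor)})
    out = pd.DataFrame(rows).set_index("extracted")
    out["duplicate_match"] = out["matched_signature"].duplicated(keep=False)
    if out["duplicate_match"].any():
        log.warning("match_cosmic: multiple extracted profiles matched the "
                    "same reference signature")
    return out


def assign_samples(
    signature_set: SignatureSet,
    groups: Mapping[str, str] | None = None,
) -> tuple[list[SampleSignatureCall], pd.DataFrame]:
    """Dominant-exposure signature call per sample + per-group frequencies.

    Each sample is labelled by the matched reference index of its largest
    exposure; exact ties resolve to the lowest reference index (logged). The
    frequency table gives, per group, the percentage of samples dominated by
    each reference signature. With no ``groups`` mapping all samples form
    one ``"all"`` group.
    """
    if signature_set.cosmic_match is None:
        raise ValueError("run match_cosmic before assign_samples")
    matched = signature_set.cosmic_match["matched_signature"]
    expo = signature_set.exposures()
    calls: list[SampleSignatureCall] = []
    for sample in expo.columns:
        fractions = expo[sample]
        top = fractions.max()
        winners = [matched[c] for c in fractions.index if fractions[c] == top]
        if len(winners) > 1:
            log.info("assign_samples: tied exposures for %s; using lowest "
                     "reference index", sample)
        calls.append(SampleSignatureCall(sample, int(min(winners)), float(top)))

    labels = {c.sample_id: (groups or {}).get(c.sample_id, "all") for c in calls}
    freq = (
        pd.DataFrame({
            "group": [labels[c.sample_id] for c in calls],
            "signature": [c.dominant_signature for c in calls],
        })
        .groupby(["group", "signature"]).size().unstack(fill_value=0)
    )
    freq = freq.div(freq.sum(axis=1), axis=0) * 100.0
    return calls, freq
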