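"""Mutation spectra and NMF signature decomposition.

A tumor's somatic SNVs are binned into the 96 pyrimidine-normalized
trinucleotide channels (and the six substitution-class marginals). Spectra
can be normalized against the reference exome's 3-mer frequencies, tested
for deviation from a cohort background with a Pearson chi-square test
(df = 5 over the six classes), and a cohort matrix of spectra decomposed
into signatures and exposures by non-negative matrix factorization with
multiplicative updates under the generalized Kullback-Leibler divergence —
the convention for count data in mutation-signature work. The factorization
is restarted from several random initializations and the best restart kept;
the number of signatures is swept (2-4 by default) and chosen from the
pairwise differentiation report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .contexts import CHANNELS_96, CHANNEL_CLASS, CHANNEL_INDEX, SUB_CLASSES, \
    normalize_snv
from .genome import GenomeModel

_EPS = np.finfo(float).tiny


@dataclass
class MutationSpectrum:
    """6-class and 96-channel substitution counts for one tumor."""

    tumor_id: str
    channel_counts: np.ndarray  # (96,), aligned to CHANNELS_96
    normalization: str = "raw"  # "raw" | "3mer-normalized"
    n_skipped: int = 0  # calls dropped for malformed context

    def __post_init__(self) -> None:
        arr = np.asarray(self.channel_counts, dtype=float)
        if arr.shape != (96,):
            raise ValueError("channel counts must have shape (96,)")
        if (arr < 0).any():
            raise ValueError("channel counts must be non-negative")
        self.channel_counts = arr

    @property
    def class_counts(self) -> pd.Series:
        """Six-class marginal (column sums of the 96-channel table)."""
        marg = pd.Series(0.0, index=list(SUB_CLASSES))
        for cls, val in zip(CHANNEL_CLASS, self.channel_counts):
            marg[cls] += val
        return marg

    @property
    def total(self) -> float:
        return float(self.channel_counts.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.channel_counts, index=list(CHANNELS_96))


def build_spectrum(calls: pd.DataFrame, tumor_id: str = "") -> MutationSpectrum:
    """Count a tumor's SNVs into the 96 canonical channels.

    Calls whose reference base is a purine are reverse-complemented into
    the pyrimidine classes via their flanking bases. Rows with malformed
    context strings are skipped (counted in ``n_skipped``) with a warning.
    """
    counts = np.zeros(96)
    skipped = 0
    snv = calls[calls["vclass"] == "SNV"] if "vclass" in calls else calls
    for rec in snv.itertuples():
        ctx = rec.context
        try:
            if ctx not in CHANNEL_INDEX:
                # purine-reference or denormalized context: rebuild from parts
                ctx = normalize_snv(ctx[2], ctx[4], ctx[0], ctx[6])
            counts[CHANNEL_INDEX[ctx]] += 1
        except (ValueError, IndexError, TypeError):
            skipped += 1
    if skipped:
        warnings.warn(f"skipped {skipped} SNV(s) with malformed context",
                      stacklevel=2)
    return MutationSpectrum(tumor_id=tumor_id, channel_counts=counts,
                            n_skipped=skipped)


def normalize_spectrum(spec: MutationSpectrum,
                       genome: GenomeModel) -> MutationSpectrum:
    """Normalize a raw spectrum by the exome's 3-mer context frequencies.

    Each channel is divided by the reference frequency of its 3-mer and the
    result rescaled to sum to 1 (when the raw spectrum is non-empty).
    """
    if spec.normalization != "raw":
        raise ValueError("spectrum is already normalized")
    freqs = genome.trinuc_freqs
    zero = np.flatnonzero(freqs <= 0)
    if zero.size:
        raise ValueError(
            f"zero reference frequency for channel {CHANNELS_96[zero[0]]}")
    weights = spec.channel_counts / freqs
    total = weights.sum()
    if total > 0:
        weights = weights / total
    return MutationSpectrum(tumor_id=spec.tumor_id, channel_counts=weights,
                            normalization="3mer-normalized",
                            n_skipped=spec.n_skipped)


def chi2_background_test(
    spec: MutationSpectrum, background: MutationSpectrum
) -> dict:
    """Pearson chi-square of a tumor's 6-class counts against the cohort
    background proportions (df = 5).

    Tumors with fewer than six SNVs are flagged ``underpowered`` but still
    tested.
    """
    obs = spec.class_counts.to_numpy()
    bg = background.class_counts.to_numpy()
    if bg.sum() <= 0:
        raise ValueError("background spectrum has zero total")
    expected = obs.sum() * bg / bg.sum()
    stat, p = stats.chisquare(obs, expected)
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "df": 5,
        "underpowered": bool(obs.sum() < 6),
    }


def pooled_background(spectra: list[MutationSpectrum],
                      exclude: str | None = None) -> MutationSpectrum:
    """Cohort background = pooled counts across all samples.

    By default the tested tumor is included in the pool; pass ``exclude``
    to leave one tumor out.
    """
    counts = np.zeros(96)
    for s in spectra:
        if exclude is not None and s.tumor_id == exclude:
            continue
        counts += s.channel_counts
    return MutationSpectrum(tumor_id="background", channel_counts=counts)


# ---------------------------------------------------------------------------
# NMF


@dataclass
class SignatureModel:
    """NMF factorization of a 96 x samples spectrum matrix.

    ``signatures`` is column-stochastic (96 x r); ``exposures`` (r x samples)
    is rescaled compensatorily so signatures @ exposures approximates the
    input counts.
    """

    rank: int
    signatures: pd.DataFrame
    exposures: pd.DataFrame
    restart_errors: list[float]
    chosen_restart: int
    objective_trajectory: list[float] = field(default_factory=list)

    @property
    def reconstruction_error(self) -> float:
        return self.restart_errors[self.chosen_restart]


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH)."""
    WH = np.maximum(WH, _EPS)
    mask = V > 0
    return float((V[mask] * np.log(V[mask] / WH[mask])).sum()
                 - V.sum() + WH.sum())


def _mu_kl(V, W, H, max_iter, tol):
    """Multiplicative updates for KL-NMF; returns W, H and the objective
    trajectory (non-increasing by construction of the updates)."""
    traj = [_kl_divergence(V, W @ H)]
    for _ in range(max_iter):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = np.maximum(W @ H, _EPS)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        traj.append(_kl_divergence(V, W @ H))
        if abs(traj[-2] - traj[-1]) <= tol * max(abs(traj[-2]), _EPS):
            break
    return W, H, traj


def _mu_frobenius(V, W, H, max_iter, tol):
    traj = [float(((V - W @ H) ** 2).sum())]
    for _ in range(max_iter):
        H *= (W.T @ V) / np.maximum(W.T @ W @ H, _EPS)
        W *= (V @ H.T) / np.maximum(W @ H @ H.T, _EPS)
        traj.append(float(((V - W @ H) ** 2).sum()))
        if abs(traj[-2] - traj[-1]) <= tol * max(abs(traj[-2]), _EPS):
            break
    return W, H, traj


def nmf_decompose(matrix: pd.DataFrame | np.ndarray, r: int,
                  restarts: int = 10, seed: int = 0,
                  objective: str = "kl", max_iter: int = 2000,
                  tol: float = 1e-6) -> SignatureModel:
    """Decompose a 96 x samples count matrix into r signatures by NMF.

    Runs ``restarts`` multiplicative-update fits from distinct random
    initializations and keeps the restart with the lowest reconstruction
    error. Fitted signatures are column-normalized to probability vectors,
    with exposures rescaled compensatorily.
    """
    V = np.asarray(matrix, dtype=float)
    if V.ndim != 2:
        raise ValueError("spectrum matrix must be 2-D (channels x samples)")
    if (V < 0).any():
        raise ValueError("spectrum matrix must be non-negative")
    n_ch, n_samp = V.shape
    if not 1 <= r <= min(n_ch, n_samp):
        raise ValueError(f"rank r={r} out of range for a {V.shape} matrix")
    zero_cols = np.flatnonzero(V.sum(axis=0) == 0)
    if zero_cols.size:
        names = getattr(matrix, "columns", range(n_samp))
        raise ValueError(f"all-zero sample column: {list(names)[zero_cols[0]]}")
    update = _mu_kl if objective == "kl" else _mu_frobenius

    best = None
    errors = []
    for k in range(restarts):
        rng = np.random.default_rng([seed, k])
        W0 = rng.uniform(0.1, 1.0, (n_ch, r)) * np.sqrt(V.mean() / r)
        # identical initial exposure per sample keeps the fit exactly
        # equivariant under sample permutation
        H0 = np.tile(rng.uniform(0.1, 1.0, (r, 1)) * np.sqrt(V.mean() / r),
                     (1, n_samp))
        W, H, traj = update(V, W0, H0, max_iter, tol)
        errors.append(traj[-1])
        if best is None or traj[-1] < best[2][-1]:
            best = (W, H, traj, k)
    W, H, traj, chosen = best
    scale = np.maximum(W.sum(axis=0), _EPS)
    W = W / scale
    H = H * scale[:, None]
    sig_names = [f"S{i + 1}" for i in range(r)]
    samples = list(getattr(matrix, "columns", range(n_samp)))
    return SignatureModel(
        rank=r,
        signatures=pd.DataFrame(W, index=list(CHANNELS_96)[:n_ch],
                                columns=sig_names),
        exposures=pd.DataFrame(H, index=sig_names, columns=samples),
        restart_errors=errors,
        chosen_restart=chosen,
        objective_trajectory=traj,
    )


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def signature_differentiation(model: SignatureModel) -> dict:
    """Pairwise cosine similarities between fitted signatures.

    The summary statistic is the maximum pairwise similarity: lower means
    better-differentiated signatures.
    """
    W = model.signatures.to_numpy()
    names = list(model.signatures.columns)
    pairs = {}
    max_sim = 0.0
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            sim = cosine_similarity(W[:, i], W[:, j])
            pairs[(names[i], names[j])] = sim
            max_sim = max(max_sim, sim)
    return {"rank": model.rank, "pairwise": pairs,
            "max_similarity": max_sim if pairs else float("nan")}


def sweep_ranks(matrix, ranks=(2, 3, 4), restarts: int = 10,
                seed: int = 0) -> dict[int, dict]:
    """Fit NMF at each rank and emit the model-selection report used to
    choose r by maximum differentiation between signatures."""
    report = {}
    for r in ranks:
        model = nmf_decompose(matrix, r, restarts=restarts, seed=seed)
        diff = signature_differentiation(model)
        report[r] = {
            "reconstruction_error": model.reconstruction_error,
            "max_similarity": diff["max_similarity"],
            "model": model,
        }
    return report


def match_signatures(fitted: pd.DataFrame, truth: pd.DataFrame) -> list[tuple]:
    """Greedy maximum-cosine assignment of fitted to true signatures
    (fitted column order is arbitrary). Returns (true, fitted, cosine)."""
    sims = [
        (cosine_similarity(truth[t].to_numpy(), fitted[f].to_numpy()), t, f)
        for t in truth.columns for f in fitted.columns
    ]
    sims.sort(reverse=True, key=lambda x: x[0])
    used_t, used_f, out = set(), set(), []
    for sim, t, f in sims:
        if t in used_t or f in used_f:
            continue
        used_t.add(t)
        used_f.add(f)
        out.append((t, f, sim))
    return out
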