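"""96-channel substitution spectra and signature attribution.

Single-base substitutions are tabulated into the conventional 96 channels
(6 pyrimidine-centred substitution classes x 16 trinucleotide contexts) and
attributed to a reference signature catalogue by expectation-maximisation
under a multinomial mixture model.

Channel order is the COSMIC convention: substitution blocks
C>A, C>G, C>T, T>A, T>C, T>G, and within each block the 16 trinucleotide
contexts sorted alphabetically (A[C>A]A, A[C>A]C, ..., T[C>A]T).
Purine-centred mutations are reverse-complemented into the pyrimidine frame
before tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PYRIMIDINE_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def channel_names() -> list[str]:
    """The 96 channel labels in fixed COSMIC order, e.g. ``A[C>G]G``."""
    names = []
    for sub in PYRIMIDINE_SUBS:
        for five in BASES:
            for three in BASES:
                names.append(f"{five}[{sub}]{three}")
    return names


CHANNELS = channel_names()
_CHANNEL_INDEX = {name: i for i, name in enumerate(CHANNELS)}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def channel_of(ref: str, alt: str, context: str) -> str | None:
    """Map one substitution to its 96-channel label.

    Parameters
    ----------
    ref, alt : str
        Single reference and alternate bases.
    context : str
        The trinucleotide centred on the mutated base (reference strand).

    Returns
    -------
    The channel label, or ``None`` if any base is ambiguous (``N``) or the
    context does not match ``ref``.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(ref) != 1 or len(alt) != 1 or len(context) != 3:
        return None
    if any(b not in _COMPLEMENT for b in ref + alt + context):
        return None
    if context[1] != ref or ref == alt:
        return None
    if ref in ("G", "A"):  # purine frame: flip to the pyrimidine strand
        ref, alt, context = _COMPLEMENT[ref], _COMPLEMENT[alt], _revcomp(context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


@dataclass
class Spectrum96:
    """Counts per 96 pyrimidine-centred trinucleotide channel."""

    counts: np.ndarray
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("a 96-channel spectrum needs exactly 96 counts")
        if np.any(self.counts < 0):
            raise ValueError("negative channel counts")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=CHANNELS, name="count")


def tabulate_96(mutations: pd.DataFrame) -> Spectrum96:
    """Tabulate substitutions into a 96-channel spectrum.

    ``mutations`` must carry either a precomputed ``channel`` column or the
    triplet ``ref``, ``alt``, ``context`` from which channels are derived
    (purine-centred records are reverse-complemented).  Records with
    ambiguous bases are skipped and counted in ``n_skipped``.
    """
    counts = np.zeros(96)
    skipped = 0
    if len(mutations) == 0:
        return Spectrum96(counts)
    if "channel" in mutations.columns:
        for ch in mutations["channel"]:
            idx = _CHANNEL_INDEX.get(ch)
            if idx is None:
                skipped += 1
            else:
                counts[idx] += 1
    else:
        for ref, alt, ctx in zip(mutations["ref"], mutations["alt"], mutations["context"]):
            ch = channel_of(ref, alt, ctx)
            if ch is None:
                skipped += 1
            else:
                counts[_CHANNEL_INDEX[ch]] += 1
    return Spectrum96(counts, n_skipped=skipped)


@dataclass
class SignatureCatalogue:
    """Named probability vectors over the 96 channels."""

    signatures: pd.DataFrame  # 96 channels x signatures

    def __post_init__(self) -> None:
        mat = self.signatures
        if mat.shape[0] != 96:
            raise ValueError("catalogue must have 96 channel rows")
        sums = mat.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each signature must sum to 1")

    @property
    def names(self) -> list[str]:
        return list(self.signatures.columns)

    def matrix(self) -> np.ndarray:
        return self.signatures.to_numpy(dtype=float)

    def collinear_groups(self, min_cosine: float = 0.999) -> list[tuple[str, str]]:
        """Pairs of signatures that are effectively indistinguishable."""
        mat = self.matrix()
        norm = mat / np.linalg.norm(mat, axis=0, keepdims=True)
        cos = norm.T @ norm
        pairs = []
        for i in range(cos.shape[0]):
            for j in range(i + 1, cos.shape[0]):
                if cos[i, j] >= min_cosine:
                    pairs.append((self.names[i], self.names[j]))
        return pairs

    @classmethod
    def from_tsv(cls, path) -> "SignatureCatalogue":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.loc[CHANNELS])

    def to_tsv(self, path) -> None:
        self.signatures.to_csv(path, sep="\t", index_label="channel")


def toy_catalogue() -> SignatureCatalogue:
    """A small bundled catalogue of synthetic signatures for tests and demos.

    The vectors are constructed in code (no download needed) and are loosely
    modelled on processes seen in germ cell tumours: a flat clock-like
    process, CpG deamination, oxidative C>A damage, a T>G-rich component and
    a component concentrated at the A[C>G]G channel (the hallmark channel of
    the undescribed yolk-sac-tumour signature).  They are synthetic
    stand-ins, not COSMIC vectors.
    """
    idx = _CHANNEL_INDEX
    sigs = {}

    flat = np.ones(96)
    # mild tilt so the vector is not exactly uniform
    flat[:32] *= 1.4
    sigs["SBS5like"] = flat

    cpg = np.full(96, 0.05)
    for five in BASES:
        cpg[idx[f"{five}[C>T]G"]] = 6.0
    sigs["SBS1like"] = cpg

    oxo = np.full(96, 0.05)
    for ctx in ("T[C>A]T", "G[C>A]A", "G[C>A]T", "A[C>A]A", "T[C>A]A"):
        oxo[idx[ctx]] = 5.0
    sigs["SBS18like"] = oxo

    t2g = np.full(96, 0.05)
    for ctx in ("C[T>G]T", "A[T>G]T", "G[T>G]T"):
        t2g[idx[ctx]] = 8.0
    sigs["SBS17like"] = t2g

    acg = np.full(96, 0.02)
    acg[idx["A[C>G]G"]] = 12.0
    acg[idx["A[C>G]A"]] = 1.0
    sigs["SBSAlike"] = acg

    df = pd.DataFrame(sigs, index=CHANNELS)
    df = df / df.sum(axis=0)
    return SignatureCatalogue(df)


@dataclass
class AttributionResult:
    exposures: pd.Series
    log_likelihoods: np.ndarray
    converged: bool
    degenerate_pairs: list = field(default_factory=list)


def em_attribution(
    spectrum: Spectrum96,
    catalogue: SignatureCatalogue,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> AttributionResult:
    """Attribute a spectrum to catalogue signatures by multinomial-mixture EM.

    Exposures start uniform (the algorithm is deterministic) and are updated
    by the standard E/M steps; the log-likelihood is monotone non-decreasing
    and iteration stops when the largest exposure change falls below
    ``tol``.  Collinear signature pairs (cosine >= 0.999) are reported in
    ``degenerate_pairs``: their summed exposure is identifiable, the split
    between them is not.
    """
    x = spectrum.counts
    if x.sum() <= 0:
        raise ValueError("cannot attribute a zero-total spectrum")
    S = catalogue.matrix()  # 96 x K
    K = S.shape[1]
    if K == 0:
        raise ValueError("empty catalogue")
    w = np.full(K, 1.0 / K)
    lls = []
    converged = False
    for _ in range(max_iter):
        mix = S @ w  # 96
        mix = np.clip(mix, 1e-300, None)
        lls.append(float(x @ np.log(mix)))
        # responsibilities: channel c assigned to signature k
        resp = S * w[None, :] / mix[:, None]  # 96 x K
        w_new = (x @ resp) / x.sum()
        w_new = w_new / w_new.sum()
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            converged = True
            break
        w = w_new
    mix = np.clip(S @ w, 1e-300, None)
    lls.append(float(x @ np.log(mix)))
    return AttributionResult(
        exposures=pd.Series(w, index=catalogue.names, name="exposure"),
        log_likelihoods=np.asarray(lls),
        converged=converged,
        degenerate_pairs=catalogue.collinear_groups(),
    )


def cosine_sim(a, b) -> float:
    """Cosine similarity between two non-negative 96-channel vectors."""
    a = np.asarray(getattr(a, "counts", a), dtype=float)
    b = np.asarray(getattr(b, "counts", b), dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))
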