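"""SBS96 catalogue construction and signature refitting with a bootstrap
sparsity filter.

Catalogues count single-base substitutions in 96 trinucleotide channels under
the pyrimidine-strand convention (purine reference bases are
reverse-complemented).  Exposures are fitted by non-negative least squares;
the sparsity filter draws B multinomial bootstrap catalogues, refits each,
and drops any signature whose bootstrap contribution is indistinguishable
from the sparsity threshold: a signature is called only when the fraction of
replicates with proportion <= threshold stays below alpha.  The point fit is
then recomputed on the called subset.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .io_formats import (
    SBS96_CHANNELS,
    MutationalCatalog,
    SignatureSet,
    VariantRecord,
)

__all__ = [
    "build_catalog",
    "fit_exposures",
    "fit_with_sparsity",
    "SignatureFitResult",
    "sbs96_channel",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_CHANNEL_INDEX = {c: i for i, c in enumerate(SBS96_CHANNELS)}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def sbs96_channel(trinucleotide: str, alt: str) -> str:
    """Map a ref trinucleotide (centre = ref base) and alt base to its channel."""
    tri = trinucleotide.upper()
    alt = alt.upper()
    if len(tri) != 3 or alt not in "ACGT":
        raise ValueError(f"bad context {trinucleotide!r} > {alt!r}")
    if tri[1] in "AG":  # collapse to the pyrimidine strand
        tri, alt = _revcomp(tri), alt.translate(_COMPLEMENT)
    channel = f"{tri[0]}[{tri[1]}>{alt}]{tri[2]}"
    if channel not in _CHANNEL_INDEX:
        raise ValueError(f"invalid channel {channel!r} (ref == alt?)")
    return channel


def _fetch_context(reference, chrom: str, pos: int) -> str:
    """Trinucleotide centred on 1-based ``pos`` from a FASTA-like mapping."""
    try:
        seq = reference[chrom]
    except KeyError:
        raise ValueError(f"contig {chrom!r} absent from reference") from None
    if pos < 2:
        raise ValueError(f"{chrom}:{pos}: no 5' flanking base (contig edge)")
    window = seq[pos - 2 : pos + 1]
    tri = str(window).upper()
    if len(tri) != 3:
        raise ValueError(f"{chrom}:{pos}: no 3' flanking base (contig edge)")
    return tri


def build_catalog(
    variants: list[VariantRecord], reference, label: str = ""
) -> MutationalCatalog:
    """Build an SBS96 catalogue from SNVs and an indexed reference.

    ``reference`` is any chrom-keyed, sliceable sequence source (a
    ``pyfaidx.Fasta`` or a plain dict of strings).  Every variant's reference
    base must match the genome at its position.
    """
    counts = np.zeros(96, dtype=int)
    for v in variants:
        if not v.is_snv:
            raise ValueError(f"{v.chrom}:{v.pos}: not a single-base substitution")
        tri = _fetch_context(reference, v.chrom, v.pos)
        if tri[1] != v.ref.upper():
            raise ValueError(
                f"{v.chrom}:{v.pos}: reference base {tri[1]} does not match "
                f"variant REF {v.ref}"
            )
        counts[_CHANNEL_INDEX[sbs96_channel(tri, v.alt)]] += 1
    return MutationalCatalog(counts=counts, label=label)


def fit_exposures(catalog: MutationalCatalog, signatures: SignatureSet) -> np.ndarray:
    """Non-negative least-squares exposures (mutation units), deterministic."""
    if list(signatures.channel_order) != list(SBS96_CHANNELS):
        raise ValueError("signature channel order does not match catalogue")
    exposures, _ = nnls(signatures.matrix, catalog.counts.astype(float))
    return exposures


@dataclass
class SignatureFitResult:
    """Bootstrap-filtered signature fit for one catalogue."""

    signature_names: list[str]
    exposures: np.ndarray          # mutation units, uncalled entries zero
    called: list[str]
    bootstrap_summary: dict        # name -> {median, ci_low, ci_high} of proportion
    config: dict = field(default_factory=dict)

    @property
    def proportions(self) -> np.ndarray:
        total = self.exposures.sum()
        if total == 0:
            return np.zeros_like(self.exposures)
        return self.exposures / total

    def proportion_of(self, name: str) -> float:
        return float(self.proportions[self.signature_names.index(name)])

    def as_dict(self) -> dict:
        return {
            "called": self.called,
            "exposures": dict(zip(self.signature_names, self.exposures.round(3))),
            "proportions": dict(zip(self.signature_names, self.proportions.round(4))),
            "bootstrap_summary": self.bootstrap_summary,
            "config": self.config,
        }


def fit_with_sparsity(
    catalog: MutationalCatalog,
    signatures: SignatureSet,
    bootstraps: int = 1000,
    sparsity_threshold: float = 0.01,
    alpha: float = 0.05,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SignatureFitResult:
    """Bootstrap signature refit with a sparsity filter.

    Bootstrap catalogues are multinomial draws of the observed total with
    channel probabilities taken from the observed catalogue.  Reproducible
    for a fixed ``seed`` (or caller-supplied ``rng``).
    """
    if bootstraps < 1:
        raise ValueError("bootstraps must be >= 1")
    total = catalog.total
    if total == 0:
        raise ValueError("cannot fit an empty catalogue")
    rng = rng if rng is not None else np.random.default_rng(seed)

    probs = catalog.counts / total
    k = signatures.n_signatures
    boot_props = np.empty((bootstraps, k))
    for b in range(bootstraps):
        resampled = rng.multinomial(total, probs)
        expo, _ = nnls(signatures.matrix, resampled.astype(float))
        s = expo.sum()
        boot_props[b] = expo / s if s > 0 else 0.0

    frac_below = (boot_props <= sparsity_threshold).mean(axis=0)
    called_mask = frac_below < alpha
    called = [n for n, keep in zip(signatures.names, called_mask) if keep]

    exposures = np.zeros(k)
    if called:
        sub = signatures.subset(called)
        sub_expo, _ = nnls(sub.matrix, catalog.counts.astype(float))
        for name, e in zip(called, sub_expo):
            exposures[signatures.names.index(name)] = e

    lo, med, hi = np.percentile(boot_props, [2.5, 50.0, 97.5], axis=0)
    summary = {
        name: {
            "median": float(med[i]),
            "ci_low": float(lo[i]),
            "ci_high": float(hi[i]),
        }
        for i, name in enumerate(signatures.names)
    }
    return SignatureFitResult(
        signature_names=list(signatures.names),
        exposures=exposures,
        called=called,
        bootstrap_summary=summary,
        config={
            "bootstraps": bootstraps,
            "sparsity_threshold": sparsity_threshold,
            "alpha": alpha,
            "seed": seed,
        },
    )
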