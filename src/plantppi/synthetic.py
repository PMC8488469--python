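"""Self-contained synthetic datasets with planted, tunable separability.

The generator emulates the structure the real pipeline exploits: each
protein carries a latent evolutionary direction, its profile is noise
plus a rank-1 planted component along that direction (integer-rounded
to resemble log-odds), and proteins interact when their latent
directions are strongly correlated (dot-product threshold).  With
``signal_strength`` at 0 the profiles carry no latent information and
the labels are independent of the features; raising it makes the
interaction classes separable in feature space.

Everything is a pure function of the config and its seed, so fixtures
(including PSI-BLAST-format ASCII PSSM files) regenerate identically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .evaluation import sample_negatives
from .io_formats import AA_ORDER, InteractionPair, Profile, ProteinRecord

_LATENT_DIM = 4
_N_CLUSTERS = 3
_NOISE_SD = 2.0
_PLANT_SCALE = 3.0
_SIM_THRESHOLD = 0.5
_CLIP = (-10, 12)


@dataclass
class SynthConfig:
    """Study conditions for a synthetic dataset.

    Defaults give 60 proteins and a balanced set of 150 interacting and
    150 non-interacting pairs with clearly separable planted structure.
    """

    n_proteins: int = 60
    length_range: tuple[int, int] = (50, 150)
    n_pos: int = 150
    n_neg: int = 150
    signal_strength: float = 2.0
    seed: int = 7

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError("length_range must satisfy 1 <= min <= max")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        if self.n_proteins < 2:
            raise ValueError("need at least 2 proteins")


def _rng(cfg: SynthConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, *stream]))


def gen_proteins(cfg: SynthConfig) -> list[ProteinRecord]:
    """Seeded i.i.d. sequences over the 20-letter alphabet."""
    rng = _rng(cfg, 0)
    letters = np.array(list(AA_ORDER))
    records = []
    width = len(str(cfg.n_proteins))
    for i in range(cfg.n_proteins):
        length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        seq = "".join(rng.choice(letters, size=length))
        records.append(ProteinRecord(id=f"SYN{i + 1:0{width}d}", sequence=seq))
    return records


def latent_vectors(cfg: SynthConfig, records: list[ProteinRecord]) -> dict[str, np.ndarray]:
    """Per-protein unit latent directions in profile (20-d) space.

    Latents sit near one of a few orthonormal cluster centres, so
    same-cluster proteins have high dot products and cross-cluster
    proteins near-zero ones.
    """
    rng = _rng(cfg, 1)
    centers, _ = np.linalg.qr(rng.normal(size=(_LATENT_DIM, _LATENT_DIM)))
    centers = centers[:, :_N_CLUSTERS]
    embed, _ = np.linalg.qr(rng.normal(size=(20, _LATENT_DIM)))
    latents: dict[str, np.ndarray] = {}
    for rec in records:
        c = centers[:, rng.integers(_N_CLUSTERS)]
        v = c + 0.25 * rng.normal(size=_LATENT_DIM)
        v = v / np.linalg.norm(v)
        w = embed @ v
        latents[rec.id] = w / np.linalg.norm(w)
    return latents


def gen_profile(
    record: ProteinRecord, latent: np.ndarray, cfg: SynthConfig
) -> Profile:
    """Noise + rank-1 planted structure along the protein's latent
    direction, integer-rounded and clipped to a log-odds-like range."""
    seed_id = zlib.crc32(record.id.encode())
    rng = _rng(cfg, 2, seed_id)
    U = len(record)
    noise = rng.normal(0.0, _NOISE_SD, size=(U, 20))
    weights = rng.uniform(0.5, 1.5, size=U)
    planted = (
        cfg.signal_strength * _PLANT_SCALE * np.outer(weights, np.asarray(latent))
    )
    values = np.clip(np.round(noise + planted), *_CLIP)
    return Profile(values=values, source="synthetic")


def gen_dataset(
    cfg: SynthConfig,
) -> tuple[list[ProteinRecord], dict[str, Profile], list[InteractionPair]]:
    """Records, profiles, and a labelled balanced pair list.

    Ground-truth interactions are the ordered pairs (a != b) whose latent
    dot product exceeds a fixed threshold; ``n_pos`` of them are sampled
    as positives and ``n_neg`` negatives are drawn from the remaining
    candidate space.
    """
    records = gen_proteins(cfg)
    latents = latent_vectors(cfg, records)
    ids = [r.id for r in records]
    W = np.array([latents[i] for i in ids])
    sims = W @ W.T
    true_edges = [
        (ids[i], ids[j])
        for i in range(len(ids))
        for j in range(len(ids))
        if i != j and sims[i, j] > _SIM_THRESHOLD
    ]
    if cfg.n_pos > len(true_edges):
        raise ValueError(
            f"requested {cfg.n_pos} positives but only {len(true_edges)} "
            "latent-correlated pairs exist; lower n_pos or add proteins"
        )
    rng = _rng(cfg, 3)
    pos_idx = rng.choice(len(true_edges), size=cfg.n_pos, replace=False)
    positives = [
        InteractionPair(*true_edges[int(i)], 1) for i in sorted(pos_idx)
    ]
    neg_seed = int(_rng(cfg, 4).integers(2**31))
    # exclude every true edge (and self pairs) so negatives are genuinely
    # uncorrelated pairs
    exclude = set(true_edges) | {(i, i) for i in ids}
    negatives = sample_negatives(ids, exclude, cfg.n_neg, seed=neg_seed)
    profiles = {r.id: gen_profile(r, latents[r.id], cfg) for r in records}
    return records, profiles, positives + negatives


def emit_ascii_pssm(
    profile: Profile, record: ProteinRecord, path: str | Path
) -> None:
    """Write an integer profile as a PSI-BLAST-format ASCII PSSM fixture.

    The file carries the header, one row per position (index, residue,
    20 log-odds, 20 zero percentages, two weight columns) and the
    trailing statistics lines, and round-trips exactly through
    ``parse_ascii_pssm``.
    """
    values = profile.values
    if not np.array_equal(values, np.round(values)):
        raise ValueError("profile values must be integers; round them first")
    if values.shape[0] != len(record):
        raise ValueError("profile row count must match the sequence length")
    header_aa = "  ".join(AA_ORDER)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        f"            {header_aa}   {header_aa}",
    ]
    for t, row in enumerate(values.astype(int), start=1):
        scores = " ".join(f"{v:3d}" for v in row)
        pcts = " ".join(f"{0:3d}" for _ in row)
        lines.append(
            f"{t:5d} {record.sequence[t - 1]}  {scores}  {pcts}  0.00 0.00"
        )
    lines += [
        "",
        "                      K         Lambda",
        "Standard Ungapped    0.1337     0.3113",
        "Standard Gapped      0.0410     0.2670",
        "PSI Ungapped         0.1337     0.3113",
        "PSI Gapped           0.0410     0.2670",
        "",
    ]
    Path(path).write_text("\n".join(lines))
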