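"""eRMSD: base-centric structural distance and sliding-window motif search.

The eRMSD compares two equal-length nucleic-acid fragments through the
relative position of every ordered base pair, expressed in base
reference frames and anisotropically scaled so that in-plane (pairing)
and normal (stacking) displacements contribute on comparable footing.
Each ordered pair (i, j) maps to a smooth 4-vector G that vanishes
beyond an ellipsoidal cutoff; the eRMSD is the root-mean-square
difference of the two G fields:

    eRMSD(A, B) = sqrt( 1/N * sum_{i != j} |G_A(i,j) - G_B(i,j)|^2 )

It is a Euclidean distance on G-space: zero on rigid motions, symmetric
and obeying the triangle inequality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import Conformation, Ensemble


@dataclass
class ErmsdConfig:
    scale_plane: float = 5.0   #: in-plane anisotropic scale, A
    scale_normal: float = 3.0  #: normal scale, A
    cutoff: float = 2.4        #: ellipsoidal cutoff in scaled units


def _fragment(conf: Conformation, authors=None) -> Conformation:
    if authors is None:
        return conf
    return Conformation(
        residues=[conf.residue_by_author(n) for n in authors],
        model_id=conf.model_id,
    )


def gvectors(conf: Conformation, cfg: ErmsdConfig | None = None) -> np.ndarray:
    """G-vector field of a fragment, shape (N, N, 4); zero on the
    diagonal and beyond the cutoff."""
    cfg = cfg or ErmsdConfig()
    frames = [conf.base_frame(r) for r in conf.residues]
    centers = np.array([f.origin for f in frames])
    n = len(frames)
    gamma = np.pi / cfg.cutoff
    G = np.zeros((n, n, 4))
    for i in range(n):
        rel = (centers - frames[i].origin) @ frames[i].axes
        rel[:, 0] /= cfg.scale_plane
        rel[:, 1] /= cfg.scale_plane
        rel[:, 2] /= cfg.scale_normal
        rho = np.linalg.norm(rel, axis=1)
        for j in range(n):
            if j == i or rho[j] >= cfg.cutoff:
                continue
            r = rho[j]
            G[i, j, :3] = np.sin(gamma * r) * rel[j] / r / gamma
            G[i, j, 3] = (1.0 + np.cos(gamma * r)) / gamma
    return G


def ermsd(frag_a: Conformation, frag_b: Conformation,
          cfg: ErmsdConfig | None = None) -> float:
    """eRMSD between two equal-length fragments (dimensionless)."""
    if len(frag_a) != len(frag_b):
        raise ValueError(
            f"fragment lengths differ: {len(frag_a)} vs {len(frag_b)}")
    ga = gvectors(frag_a, cfg)
    gb = gvectors(frag_b, cfg)
    return float(np.sqrt(np.sum((ga - gb) ** 2) / len(frag_a)))


@dataclass
class SearchHit:
    entry_id: str
    model: int
    window_start: int       # author number of the first window residue
    sequence: str
    ermsd: float

    def __post_init__(self):
        if self.ermsd < 0:
            raise ValueError("eRMSD must be non-negative")


def _windows(conf: Conformation, length: int):
    """Contiguous same-chain windows of the given residue length."""
    res = conf.residues
    start = 0
    while start + length <= len(res):
        block = res[start:start + length]
        ok = all(
            b.chain_id == block[0].chain_id
            and b.author_number == block[0].author_number + k
            for k, b in enumerate(block)
        )
        if ok:
            yield Conformation(residues=list(block), model_id=conf.model_id)
        start += 1


def scan_library(template: Conformation, library: dict[str, Ensemble],
                 threshold: float = 1.0, model_mode: str = "best",
                 cfg: ErmsdConfig | None = None) -> list[SearchHit]:
    """Sequence-independent sliding-window search of a structure library.

    Every contiguous window of template length in every model of every
    entry is scored; per entry the best (minimum-eRMSD) window is kept
    (``model_mode='first'`` restricts the scan to model 1).  Hits below
    the threshold are returned sorted by ascending eRMSD.
    """
    hits = []
    for entry_id, ens in library.items():
        models = ens.conformations if model_mode == "best" \
            else ens.conformations[:1]
        best: SearchHit | None = None
        for conf in models:
            if len(conf) < len(template):
                continue  # entry chain shorter than the template
            for window in _windows(conf, len(template)):
                score = ermsd(template, window, cfg)
                if best is None or score < best.ermsd:
                    best = SearchHit(
                        entry_id=entry_id, model=conf.model_id,
                        window_start=window.residues[0].author_number,
                        sequence=window.sequence, ermsd=score)
        if best is not None and best.ermsd < threshold:
            hits.append(best)
    return sorted(hits, key=lambda h: h.ermsd)


def hits_to_tsv(hits, path) -> None:
    with open(path, "w") as fh:
        fh.write("entry\teRMSD\tsequence\tmodel\tresidues\n")
        for h in hits:
            end = h.window_start + len(h.sequence) - 1
            fh.write(f"{h.entry_id}\t{h.ermsd:.2f}\t{h.sequence}\t"
                     f"{h.model}\t{h.window_start}-{end}\n")
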