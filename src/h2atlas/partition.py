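"""Hierarchical assignment of SNPs to functional-annotation components.

Annotations are genomic interval sets (BED, 0-based half-open).  A model is an
ordered list of components, each backed by one or more annotation tracks, and
every SNP is assigned to the *first* component whose (merged) intervals contain
it — coding before UTR before promoter before the annotation of interest, and
so on down to a catch-all "other" slot.  The resulting partition is exhaustive
and exclusive by construction, and its per-component SNP fractions are the
null expectation for the share of heritability each component explains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationTrack",
    "ModelSpec",
    "PartitionAssignment",
    "read_intervals",
    "write_intervals",
    "merge_intervals",
    "extend_from_center",
    "assign_hierarchy",
    "model_registry",
    "MODEL_REGISTRY_NAMES",
]


@dataclass
class AnnotationTrack:
    """A named set of genomic intervals, 0-based half-open, sorted per chromosome."""

    name: str
    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if np.any(self.starts >= self.ends):
            bad = int(np.flatnonzero(self.starts >= self.ends)[0])
            raise ValueError(
                f"interval {bad} of track {self.name!r} has start >= end "
                f"({self.starts[bad]} >= {self.ends[bad]})"
            )
        order = np.lexsort((self.starts, self.chroms.astype(str)))
        self.chroms = self.chroms[order]
        self.starts = self.starts[order]
        self.ends = self.ends[order]

    def __len__(self) -> int:
        return len(self.starts)

    def total_length(self) -> int:
        return int((self.ends - self.starts).sum())


@dataclass
class ModelSpec:
    """Ordered component list of a hierarchical joint model.

    ``components`` maps each component name to the annotation-track names whose
    union defines it; the final component is the fallback and needs no tracks.
    """

    name: str
    components: Sequence[tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.components]
        if len(set(names)) != len(names):
            raise ValueError("component names must be unique")

    @property
    def component_names(self) -> list[str]:
        return [c for c, _ in self.components]

    def with_slot(self, slot: str, tracks: tuple[str, ...]) -> "ModelSpec":
        """Return a copy with one component's source tracks replaced."""
        comps = [(n, tracks if n == slot else t) for n, t in self.components]
        return ModelSpec(name=self.name, components=comps)


@dataclass
class PartitionAssignment:
    """Exclusive assignment of every SNP to exactly one model component."""

    component_names: list[str]
    component_of: np.ndarray  # per-SNP component index
    fractions: np.ndarray  # per-component share of SNPs

    def __post_init__(self) -> None:
        self.component_of = np.asarray(self.component_of, dtype=np.int64)
        self.fractions = np.asarray(self.fractions, dtype=np.float64)
        if abs(self.fractions.sum() - 1.0) > 1e-12:
            raise ValueError("component fractions must sum to 1")

    @property
    def n_snps(self) -> int:
        return len(self.component_of)

    def snp_indices(self, component: str) -> np.ndarray:
        return np.flatnonzero(self.component_of == self.component_names.index(component))

    def counts(self) -> np.ndarray:
        return np.bincount(self.component_of, minlength=len(self.component_names))

    def to_frame(self, snp_ids=None) -> pd.DataFrame:
        names = np.asarray(self.component_names)[self.component_of]
        ids = snp_ids if snp_ids is not None else np.arange(self.n_snps)
        return pd.DataFrame({"snp_id": ids, "component": names})


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------


def read_intervals(path, name: str | None = None) -> AnnotationTrack:
    """Read a BED(3+) file into an AnnotationTrack.

    Overlapping input intervals are preserved; merging is an explicit step.
    """
    chroms, starts, ends = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns, got {len(parts)}")
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if s >= e:
                raise ValueError(f"{path}:{lineno}: start >= end ({s} >= {e})")
            chroms.append(parts[0])
            starts.append(s)
            ends.append(e)
    track_name = name if name is not None else str(path)
    return AnnotationTrack(
        name=track_name,
        chroms=np.asarray(chroms, dtype=object),
        starts=np.asarray(starts),
        ends=np.asarray(ends),
    )


def write_intervals(track: AnnotationTrack, path) -> None:
    df = pd.DataFrame({"chrom": track.chroms, "start": track.starts, "end": track.ends})
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------


def merge_intervals(track: AnnotationTrack) -> AnnotationTrack:
    """Union of intervals: overlapping or abutting intervals are merged."""
    if len(track) == 0:
        return track
    chroms, starts, ends = [], [], []
    for c in pd.unique(track.chroms):
        sel = track.chroms == c
        s = track.starts[sel]
        e = track.ends[sel]
        cur_s, cur_e = s[0], e[0]
        for i in range(1, len(s)):
            if s[i] <= cur_e:  # overlap or abut
                cur_e = max(cur_e, e[i])
            else:
                chroms.append(c)
                starts.append(cur_s)
                ends.append(cur_e)
                cur_s, cur_e = s[i], e[i]
        chroms.append(c)
        starts.append(cur_s)
        ends.append(cur_e)
    return AnnotationTrack(
        name=track.name,
        chroms=np.asarray(chroms, dtype=object),
        starts=np.asarray(starts),
        ends=np.asarray(ends),
    )


def extend_from_center(track: AnnotationTrack, flank: int) -> AnnotationTrack:
    """Replace each interval by [center - flank, center + flank), clamped at 0.

    center = floor((start + end) / 2).  Zero flank on odd-length intervals
    degenerates to the 1-bp window at the center; the resulting set is merged.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    centers = (track.starts + track.ends) // 2
    starts = np.maximum(centers - flank, 0)
    ends = centers + flank
    if flank == 0:
        ends = centers + 1  # keep a non-degenerate 1-bp interval at the center
        starts = centers
    return merge_intervals(
        AnnotationTrack(name=track.name, chroms=track.chroms.copy(), starts=starts, ends=ends)
    )


def _membership(chrom: np.ndarray, pos: np.ndarray, track: AnnotationTrack) -> np.ndarray:
    """Half-open containment of positions in a *merged* track."""
    out = np.zeros(len(pos), dtype=bool)
    chrom = np.asarray([str(c) for c in chrom], dtype=object)
    for c in pd.unique(track.chroms):
        sel = chrom == str(c)
        if not sel.any():
            continue
        tsel = track.chroms == c
        starts = track.starts[tsel]
        ends = track.ends[tsel]
        idx = np.searchsorted(starts, pos[sel], side="right") - 1
        ok = idx >= 0
        hit = np.zeros(int(sel.sum()), dtype=bool)
        hit[ok] = pos[sel][ok] < ends[idx[ok]]
        out[sel] = hit
    return out


def assign_hierarchy(
    chrom: np.ndarray,
    pos: np.ndarray,
    model: ModelSpec,
    tracks: Mapping[str, AnnotationTrack],
) -> PartitionAssignment:
    """Assign every SNP to the first model component whose intervals contain it.

    Components are resolved in model order; a SNP inside several annotations
    lands in the earliest one.  SNPs contained in no track (including SNPs on
    chromosomes absent from every track) fall to the final fallback component.
    """
    pos = np.asarray(pos)
    n = len(pos)
    comp_of = np.full(n, -1, dtype=np.int64)
    for ci, (cname, track_names) in enumerate(model.components):
        if not track_names:
            continue  # fallback slot
        member = np.zeros(n, dtype=bool)
        for tname in track_names:
            if tname not in tracks:
                raise KeyError(f"model component {cname!r} needs missing track {tname!r}")
            member |= _membership(chrom, pos, merge_intervals(tracks[tname]))
        member &= comp_of < 0
        comp_of[member] = ci
    fallback = len(model.components) - 1
    unassigned = comp_of < 0
    if unassigned.any():
        logger.debug("%d SNPs fell to fallback component %r", int(unassigned.sum()), model.components[fallback][0])
    comp_of[unassigned] = fallback
    fractions = np.bincount(comp_of, minlength=len(model.components)) / n
    return PartitionAssignment(
        component_names=model.component_names,
        component_of=comp_of,
        fractions=fractions,
    )


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------

_BACKGROUND = [("coding", ("coding",)), ("utr", ("utr",)), ("promoter", ("promoter",))]
_TAIL = [("intron", ("intron",)), ("other", ())]


def _spec(name: str, middle: list[tuple[str, tuple[str, ...]]], tail=None) -> ModelSpec:
    return ModelSpec(name=name, components=_BACKGROUND + middle + (tail if tail is not None else _TAIL))


_REGISTRY: dict[str, ModelSpec] = {
    # single-annotation model: coding > UTR > promoter > annotation of
    # interest > DHS > intron > other
    "marginal7": _spec("marginal7", [("focal", ("focal",)), ("dhs", ("dhs",))]),
    # tissue-defined androgen-receptor sites, normal-only vs tumour-only
    # (each flanked 5 kb from interval centers upstream of this model)
    "tumour_normal8": _spec(
        "tumour_normal8",
        [("normal_only", ("normal_only",)), ("tumour_only", ("tumour_only",)), ("dhs", ("dhs",))],
    ),
    # androgen-receptor sites from tissue vs from the LNCaP cell line
    "arbs_pair7": _spec("arbs_pair7", [("arbs", ("arbs",)), ("dhs", ("dhs",))]),
    # pairwise open-chromatin comparison of two cell lines
    "dhs_pairwise9": _spec(
        "dhs_pairwise9",
        [
            ("dhs_cell_a_only", ("dhs_cell_a_only",)),
            ("dhs_shared", ("dhs_shared",)),
            ("dhs_cell_b_only", ("dhs_cell_b_only",)),
            ("dhs_other", ("dhs_other",)),
        ],
    ),
    # enhancer or super-enhancer of one cell type in the interest slot
    "enhancer7": _spec("enhancer7", [("enhancer", ("enhancer",)), ("dhs", ("dhs",))]),
    # re-evaluation of one annotation conditional on the selected model
    "conditional10": _spec(
        "conditional10",
        [
            ("lncap_h3k27ac", ("lncap_h3k27ac",)),
            ("arbs", ("arbs",)),
            ("dhs_cancer", ("dhs_cancer",)),
            ("focal", ("focal",)),
            ("dhs", ("dhs",)),
        ],
    ),
    # the 15-group joint model over all marginally significant annotation groups
    "full15": ModelSpec(
        name="full15",
        components=_BACKGROUND
        + [
            ("lncap_h3k27ac", ("lncap_h3k27ac",)),
            ("arbs", ("arbs",)),
            ("lncap_foxa1", ("lncap_foxa1",)),
            ("lncap_h3k4me1", ("lncap_h3k4me1",)),
            ("lncap_dhs", ("lncap_dhs",)),
            ("dhs_prostate", ("dhs_prostate",)),
            ("dhs_cancer", ("dhs_cancer",)),
            ("h3k4me1_other", ("h3k4me1_other",)),
            ("h3k27ac_other", ("h3k27ac_other",)),
            ("dhs_other", ("dhs_other",)),
            ("repressed", ("repressed",)),
            ("all_other", ()),
        ],
    ),
    # components significant in the full model plus the coding-proximal background
    "selected8": ModelSpec(
        name="selected8",
        components=_BACKGROUND
        + [
            ("lncap_h3k27ac", ("lncap_h3k27ac",)),
            ("arbs", ("arbs",)),
            ("dhs_cancer", ("dhs_cancer",)),
            ("repressed", ("repressed",)),
            ("all_other", ()),
        ],
    ),
    # variance explained by the known association hits vs the rest of the genome
    "gwas_hits2": ModelSpec(name="gwas_hits2", components=[("gwas_hits", ("gwas_hits",)), ("rest", ())]),
}

MODEL_REGISTRY_NAMES = sorted(_REGISTRY)


def model_registry(name: str) -> ModelSpec:
    """Look up a named hierarchical model; raises listing the registry on miss."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available models: {', '.join(MODEL_REGISTRY_NAMES)}"
        ) from None
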