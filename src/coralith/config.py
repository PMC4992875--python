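"""Pipeline configuration and the index-design oligo arithmetic.

A single YAML document configures a run end to end; loading validates
every referenced file and parameter range, and ``load -> dump -> load``
round-trips exactly.

:func:`design_index_oligos` reproduces the cost arithmetic of dual
indexing: with forward and reverse index oligos combined combinatorially,
a x b oligos address a*b samples, so 96 samples need only 10 + 10 = 20
oligos, against 384 forward oligos (one per sample x marker) for a
single-index-per-marker design.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cluster import ChimeraParams
from .errors import ConfigError, ParameterError
from .filters import FilterParams
from .markers import MarkerSpec, default_marker_panel, validate_panel
from .readprep import QCParams


@dataclass(frozen=True)
class IndexDesign:
    n_samples: int
    n_markers: int
    scheme: str
    forward_oligos: int
    reverse_oligos: int
    total_oligos: int


def design_index_oligos(n_samples: int, n_markers: int,
                        scheme: str = "dual_index") -> IndexDesign:
    """Minimal oligo count for addressing ``n_samples`` libraries.

    ``dual_index``: minimise a+b over positive integers with a*b >=
    n_samples (ties broken toward the squarest design). ``single_index_per_marker``:
    one forward oligo per sample per marker plus one reverse per marker.
    """
    if n_samples < 1 or n_markers < 1:
        raise ParameterError("n_samples and n_markers must be >= 1")
    if scheme == "dual_index":
        best: tuple[int, int, int, int] | None = None  # (a+b, |a-b|, a, b)
        for a in range(1, int(math.isqrt(n_samples)) + 2):
            b = -(-n_samples // a)  # ceil
            cand = (a + b, abs(a - b), a, b)
            if best is None or cand < best:
                best = cand
        _, _, a, b = best
        return IndexDesign(n_samples, n_markers, scheme, a, b, a + b)
    if scheme == "single_index_per_marker":
        fwd = n_samples * n_markers
        return IndexDesign(n_samples, n_markers, scheme, fwd, n_markers,
                           fwd + n_markers)
    raise ParameterError(f"unknown scheme {scheme!r}")


@dataclass(frozen=True)
class ClassifyParams:
    k: int = 8
    n_bootstrap: int = 100
    subsample_fraction: float = 1 / 8
    confidence_threshold: float = 0.7


@dataclass(frozen=True)
class EvolutionParams:
    tree: str | None = None     # newick path, branch lengths in my
    traits: str | None = None   # tip\tstate TSV path
    n_maps: int = 1000
    variant: str = "equal_rates"
    root_prior: str = "stationary"


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "coralith_out"
    manifest: str = "manifest.tsv"
    #: marker name -> reference FASTA (lineage-header dialect) for taxonomy
    references: dict[str, str] = field(default_factory=dict)
    markers: list[MarkerSpec] = field(default_factory=default_marker_panel)
    qc: QCParams = field(default_factory=QCParams)
    chimera: ChimeraParams = field(default_factory=ChimeraParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    filters: FilterParams = field(default_factory=FilterParams)
    evolution: EvolutionParams = field(default_factory=EvolutionParams)

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "manifest": self.manifest,
            "references": dict(self.references),
            "markers": [asdict(m) for m in self.markers],
            "qc": asdict(self.qc),
            "chimera": asdict(self.chimera),
            "classify": asdict(self.classify),
            "filters": asdict(self.filters),
            "evolution": asdict(self.evolution),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        markers = ([MarkerSpec(**m) for m in d["markers"]]
                   if "markers" in d else default_marker_panel())
        return cls(
            seed=int(d.get("seed", 0)),
            output_dir=d.get("output_dir", "coralith_out"),
            manifest=d.get("manifest", "manifest.tsv"),
            references=dict(d.get("references", {})),
            markers=markers,
            qc=QCParams(**d.get("qc", {})),
            chimera=ChimeraParams(**d.get("chimera", {})),
            classify=ClassifyParams(**d.get("classify", {})),
            filters=FilterParams(**d.get("filters", {})),
            evolution=EvolutionParams(**d.get("evolution", {})),
        )

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate(self, base: Path | None = None) -> None:
        """Check file references and panel distinguishability."""
        base = base or Path(".")
        validate_panel(self.markers)

        def _exists(p: str | None, what: str) -> None:
            if p is not None and not (base / p).exists():
                raise ConfigError(f"{what} not found: {p}")

        _exists(self.manifest, "manifest")
        for marker, ref in self.references.items():
            _exists(ref, f"reference for {marker}")
        _exists(self.evolution.tree, "tree")
        _exists(self.evolution.traits, "trait table")
        if (self.evolution.tree is None) != (self.evolution.traits is None):
            raise ConfigError("evolution needs both a tree and a trait table")
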