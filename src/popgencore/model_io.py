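"""Population-model files: named assignments of individuals to populations.

A *model* names a set of populations, assigns individual (sample) IDs to
each, and optionally carries a newick-like population-tree string.  A single
JSON *model file* stores any number of models, so one document can hold e.g.
a ``2pop`` and a ``4pop`` sampling scheme for the same cohort; the same
individual may appear in several models (but never in two populations of the
same model).  Every downstream step — site filtering, FST, the SFS, the
IMa3/G-PhoCS/treemix exporters — takes a model and pulls populations and
individuals from it, so sample bookkeeping lives in exactly one place.

File dialect: a UTF-8 JSON list of model objects, each
``{"name": str, "tree": str|null, "pops": {popName: {"inds": [str, ...]}}}``.
Population order is the key order of the file; unknown extra keys are
preserved on read and re-emitted on write.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

__all__ = [
    "ModelError",
    "PopulationModel",
    "ModelFile",
    "create_model",
    "read_model_file",
    "write_model_file",
    "model_individuals",
    "model_sizes",
]


class ModelError(ValueError):
    """Invalid model structure (duplicate names, empty populations, ...)."""


def _check_tree(tree: str) -> None:
    depth = 0
    for ch in tree:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ModelError(f"unbalanced parentheses in tree: {tree!r}")
    if depth != 0:
        raise ModelError(f"unbalanced parentheses in tree: {tree!r}")


@dataclass
class PopulationModel:
    """Ordered assignment of individuals to named populations."""

    name: str
    pops: dict[str, list[str]]
    tree: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise ModelError("model name must be non-empty")
        if not self.pops:
            raise ModelError(f"model {self.name!r} has no populations")
        seen: set[str] = set()
        for pop, inds in self.pops.items():
            if not inds:
                raise ModelError(f"population {pop!r} in model {self.name!r} is empty")
            for ind in inds:
                if ind in seen:
                    raise ModelError(
                        f"individual {ind!r} assigned to two populations of model {self.name!r}"
                    )
                seen.add(ind)
        if self.tree is not None:
            _check_tree(self.tree)

    @property
    def pop_names(self) -> list[str]:
        return list(self.pops)

    @property
    def n_pops(self) -> int:
        return len(self.pops)

    def individuals(self) -> list[str]:
        """All individual IDs, concatenated over populations in model order."""
        return [ind for inds in self.pops.values() for ind in inds]

    def sizes(self, ploidy: int = 2) -> dict[str, int]:
        """Haploid sample size per population (``ploidy`` x individuals)."""
        if ploidy < 1:
            raise ModelError("ploidy must be >= 1")
        return {pop: ploidy * len(inds) for pop, inds in self.pops.items()}

    def population_of(self, individual: str) -> str:
        for pop, inds in self.pops.items():
            if individual in inds:
                return pop
        raise KeyError(individual)


@dataclass
class ModelFile:
    """Ordered collection of uniquely named models."""

    models: dict[str, PopulationModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, model in self.models.items():
            if name != model.name:
                raise ModelError(f"model keyed {name!r} is named {model.name!r}")

    def add(self, model: PopulationModel) -> None:
        if model.name in self.models:
            raise ModelError(f"duplicate model name {model.name!r}")
        self.models[model.name] = model

    def __getitem__(self, name: str) -> PopulationModel:
        return self.models[name]

    def __iter__(self) -> Iterator[PopulationModel]:
        return iter(self.models.values())

    def __len__(self) -> int:
        return len(self.models)


def create_model(
    name: str,
    pops: Mapping[str, Sequence[str]],
    tree: str | None = None,
) -> PopulationModel:
    """Build and validate a model from population → individual-ID lists."""
    return PopulationModel(name=name, pops={p: list(i) for p, i in pops.items()}, tree=tree)


def model_individuals(model: PopulationModel) -> list[str]:
    return model.individuals()


def model_sizes(model: PopulationModel, ploidy: int = 2) -> dict[str, int]:
    return model.sizes(ploidy)


_RESERVED = {"name", "tree", "pops"}


def read_model_file(path) -> ModelFile:
    """Read a JSON model file; rejects duplicate model names and empty files."""
    with open(path, encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelError(f"malformed JSON in {path}: {exc}") from exc
    if not isinstance(data, list) or not data:
        raise ModelError(f"{path}: expected a non-empty JSON list of models")
    mf = ModelFile()
    for obj in data:
        if not isinstance(obj, dict) or "name" not in obj or "pops" not in obj:
            raise ModelError(f"{path}: model object missing required keys 'name'/'pops'")
        pops: dict[str, list[str]] = {}
        for pop, body in obj["pops"].items():
            if not isinstance(body, dict) or "inds" not in body:
                raise ModelError(f"{path}: population {pop!r} missing 'inds'")
            pops[pop] = [str(i) for i in body["inds"]]
        extra = {k: v for k, v in obj.items() if k not in _RESERVED}
        model = PopulationModel(
            name=str(obj["name"]), pops=pops, tree=obj.get("tree"), extra=extra
        )
        mf.add(model)
    return mf


def write_model_file(mf: ModelFile, path) -> None:
    """Write a model file; ``write ∘ read`` is the identity on the data model."""
    if not len(mf):
        raise ModelError("refusing to write an empty model file")
    out = []
    for model in mf:
        obj: dict = {"name": model.name, "tree": model.tree}
        obj["pops"] = {pop: {"inds": list(inds)} for pop, inds in model.pops.items()}
        obj.update(model.extra)
        out.append(obj)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(out, fh, indent=2)
        fh.write("\n")
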