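"""Random and balanced-scaffold train/validation/test splits.

Scaffold splitting keeps every Bemis-Murcko scaffold inside a single
partition, so the test set holds scaffolds never seen in training —
the probe for inter-scaffold generalization.  The whole protocol is
repeated over many seeds (30 by default, seeds 0..29) so downstream
comparisons can be made statistically rather than from a single split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .data import CuratedDataset

__all__ = ["SplitManifest", "random_split", "scaffold_split", "split_protocol"]


class SplitError(ValueError):
    """Raised when a dataset cannot populate all three partitions."""


@dataclass
class SplitManifest:
    """One seed's disjoint train/val/test molecule-id lists."""

    dataset_name: str
    method: Literal["scaffold", "random"]
    seed: int
    ratios: tuple[float, float, float]
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]

    def partitions(self) -> dict[str, list[str]]:
        return {"train": self.train_ids, "val": self.val_ids, "test": self.test_ids}

    def save(self, path: str | Path) -> None:
        d = asdict(self)
        d["ratios"] = list(self.ratios)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SplitManifest":
        d = json.loads(Path(path).read_text())
        d["ratios"] = tuple(d["ratios"])
        return cls(**d)


def _check_ratios(ratios: Sequence[float]) -> tuple[float, float, float]:
    if len(ratios) != 3 or not np.isclose(sum(ratios), 1.0):
        raise ValueError(f"ratios must be three fractions summing to 1, got {ratios}")
    return tuple(float(r) for r in ratios)  # type: ignore[return-value]


def random_split(
    dataset: CuratedDataset,
    ratios: Sequence[float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitManifest:
    """Seeded uniform shuffle split with floor-arithmetic sizes.

    train gets floor(r_train * n) molecules, val floor(r_val * n), test the
    remainder.  Deterministic per seed.
    """
    ratios = _check_ratios(ratios)
    n = len(dataset)
    n_train, n_val = int(ratios[0] * n), int(ratios[1] * n)
    if min(n_train, n_val, n - n_train - n_val) < 1:
        raise SplitError(f"dataset of size {n} cannot populate all partitions")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    ids = np.array(dataset.ids)
    return SplitManifest(
        dataset_name=dataset.name,
        method="random",
        seed=seed,
        ratios=ratios,
        train_ids=list(ids[order[:n_train]]),
        val_ids=list(ids[order[n_train : n_train + n_val]]),
        test_ids=list(ids[order[n_train + n_val :]]),
    )


def scaffold_split(
    dataset: CuratedDataset,
    ratios: Sequence[float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitManifest:
    """Balanced scaffold split: no scaffold crosses partitions.

    Molecules are grouped by scaffold (acyclic molecules form the single
    empty-scaffold group).  Groups bigger than half the target test size are
    queued first in deterministic (size-desc, then lexicographic) order; the
    remaining groups are shuffled with the seed.  Groups then fill train
    until its target count is reached, then val, then test.  Partition sizes
    deviate from the ratios only by scaffold-group granularity.
    """
    ratios = _check_ratios(ratios)
    groups: dict[str, list[str]] = {}
    for mol in dataset.molecules:
        groups.setdefault(mol.scaffold, []).append(mol.id)
    if len(groups) < 3:
        raise SplitError(f"need >= 3 scaffold groups, found {len(groups)}")

    n = len(dataset)
    n_train_target = ratios[0] * n
    n_val_target = ratios[1] * n
    big_cutoff = ratios[2] * n / 2

    big = sorted(
        (s for s in groups if len(groups[s]) > big_cutoff),
        key=lambda s: (-len(groups[s]), s),
    )
    small = sorted(s for s in groups if len(groups[s]) <= big_cutoff)
    rng = np.random.default_rng(seed)
    rng.shuffle(small)

    train: list[str] = []
    val: list[str] = []
    test: list[str] = []
    for scaffold in big + list(small):
        members = groups[scaffold]
        if len(train) + len(members) <= n_train_target or not train:
            train.extend(members)
        elif len(val) + len(members) <= n_val_target or not val:
            val.extend(members)
        else:
            test.extend(members)
    for part, name in ((val, "val"), (test, "test")):
        if not part:
            raise SplitError(f"scaffold split could not populate the {name} partition")
    return SplitManifest(
        dataset_name=dataset.name,
        method="scaffold",
        seed=seed,
        ratios=ratios,
        train_ids=train,
        val_ids=val,
        test_ids=test,
    )


def split_protocol(
    dataset: CuratedDataset,
    methods: Sequence[str] = ("scaffold", "random"),
    n_seeds: int = 30,
    ratios: Sequence[float] = (0.8, 0.1, 0.1),
    out_dir: str | Path | None = None,
) -> list[SplitManifest]:
    """Produce every (method, seed) manifest for seeds 0..n_seeds-1.

    With both methods and 30 seeds this yields the 60 manifests reused
    identically by all downstream experiments.  When ``out_dir`` is given the
    manifests are also persisted as JSON.
    """
    splitters = {"scaffold": scaffold_split, "random": random_split}
    manifests = []
    for method in methods:
        if method not in splitters:
            raise ValueError(f"unknown split method {method!r}")
        for seed in range(n_seeds):
            try:
                manifest = splitters[method](dataset, ratios=ratios, seed=seed)
            except SplitError as exc:
                raise SplitError(f"{method} split failed at seed {seed}: {exc}") from exc
            manifests.append(manifest)
            if out_dir is not None:
                out = Path(out_dir)
                out.mkdir(parents=True, exist_ok=True)
                manifest.save(out / f"{dataset.name}_{method}_{seed}.json")
    return manifests
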