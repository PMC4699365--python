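"""Deterministic synthetic-screen generator.

Emulates a miniature high-content screen in the import dialect: genes
(grouping objects), images (metadata with URL link-outs) and cells
(descriptive objects carrying numeric features), plus a binary hit-label
file and a ground-truth JSON.  Feature values are independent Gaussians,
``Normal(base_mean + shift * base_sd, base_sd)`` per cell, where the
shift is the planted per-(hit gene, feature) effect size in within-gene
standard-deviation units.  An optional paired-feature channel plants a
linear relation ``y = a * x + Normal(0, sd)`` at the cell level so
regression fits have a known slope.

Everything is driven by one integer seed through a specified PRNG
(NumPy's PCG64); the same truth object always produces byte-identical
files.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import GenerationError

__all__ = [
    "SyntheticScreenTruth",
    "GeneratedScreen",
    "CorruptedFixture",
    "CORRUPTION_VARIANTS",
    "generate_screen",
    "generate_corrupted",
]

CELLS_PER_IMAGE = 25
URL_TEMPLATE = "https://images.invalid/screens/{image_id}"

CORRUPTION_VARIANTS = ("missing-type-row", "bad-number-cell",
                       "unknown-label-id", "ragged-row")


@dataclass
class SyntheticScreenTruth:
    """Ground-truth parameters for one synthetic screen.

    ``effect_sizes`` maps ``(gene_id, feature_name)`` to a mean shift in
    units of that feature's within-gene standard deviation.
    """

    n_genes: int = 50
    cells_per_gene: int | Sequence[int] = 100
    n_features: int = 10
    hit_genes: tuple[str, ...] = ()
    effect_sizes: dict[tuple[str, str], float] = field(default_factory=dict)
    base_means: tuple[float, ...] = ()
    base_sds: tuple[float, ...] = ()
    seed: int = 0
    missing_rate: float = 0.0
    paired_slope: float | None = None     # last feature = a*first + noise
    paired_noise_sd: float = 0.1

    @classmethod
    def default(cls, n_genes: int = 50, cells_per_gene=100,
                n_features: int = 10, n_hits: int = 5,
                effect_size: float = 2.0, seed: int = 0,
                **overrides) -> "SyntheticScreenTruth":
        """Standard study conditions: ``n_hits`` hit genes (chosen by the
        seeded PRNG) with ``effect_size`` planted on the first feature."""
        if n_genes < 1 or n_features < 1:
            raise GenerationError("need at least 1 gene and 1 feature")
        rng = np.random.default_rng(seed)
        genes = [f"g{i:04d}" for i in range(1, n_genes + 1)]
        if not 0 <= n_hits <= n_genes:
            raise GenerationError(
                f"n_hits={n_hits} out of range for {n_genes} genes")
        hits = tuple(sorted(
            str(g) for g in rng.choice(genes, size=n_hits, replace=False)))
        features = [f"feat_{j:02d}" for j in range(1, n_features + 1)]
        effects = {(g, features[0]): effect_size for g in hits}
        return cls(n_genes=n_genes, cells_per_gene=cells_per_gene,
                   n_features=n_features, hit_genes=hits,
                   effect_sizes=effects, seed=seed, **overrides)

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_features < 1:
            raise GenerationError("need at least 1 gene and 1 feature")
        if not self.base_means:
            # features on distinct positive scales, like real morphology
            # measurements (areas, lengths, intensities)
            self.base_means = tuple(10.0 + 5.0 * j
                                    for j in range(self.n_features))
        if not self.base_sds:
            self.base_sds = tuple(1.0 + 0.25 * j
                                  for j in range(self.n_features))
        if len(self.base_means) != self.n_features \
                or len(self.base_sds) != self.n_features:
            raise GenerationError("base_means/base_sds length mismatch")
        if any(sd <= 0 for sd in self.base_sds):
            raise GenerationError("base_sds must be positive")
        if not 0 <= self.missing_rate < 1:
            raise GenerationError("missing_rate must be in [0, 1)")
        counts = self.cell_counts()
        if any(c < 1 for c in counts.values()):
            raise GenerationError("cells_per_gene must be >= 1")
        genes = set(self.gene_ids())
        if not set(self.hit_genes) <= genes:
            raise GenerationError("hit_genes must be a subset of the genes")
        for (g, f), shift in self.effect_sizes.items():
            if g not in genes or f not in self.feature_names():
                raise GenerationError(f"effect on unknown ({g!r}, {f!r})")
            if not math.isfinite(shift):
                raise GenerationError(f"non-finite effect size for {g!r}")
        if self.paired_slope is not None and self.n_features < 2:
            raise GenerationError("paired feature needs >= 2 features")

    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(1, self.n_genes + 1)]

    def feature_names(self) -> list[str]:
        return [f"feat_{j:02d}" for j in range(1, self.n_features + 1)]

    def cell_counts(self) -> dict[str, int]:
        genes = self.gene_ids()
        if isinstance(self.cells_per_gene, int):
            return {g: self.cells_per_gene for g in genes}
        counts = list(self.cells_per_gene)
        if len(counts) != len(genes):
            raise GenerationError(
                f"per-gene cell counts: expected {len(genes)} entries, "
                f"got {len(counts)}")
        return dict(zip(genes, counts))

    def to_json_obj(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "cells_per_gene": (self.cells_per_gene
                               if isinstance(self.cells_per_gene, int)
                               else list(self.cells_per_gene)),
            "n_features": self.n_features,
            "hit_genes": list(self.hit_genes),
            "effect_sizes": {f"{g}:{f}": v
                             for (g, f), v in sorted(
                                 self.effect_sizes.items())},
            "base_means": list(self.base_means),
            "base_sds": list(self.base_sds),
            "seed": self.seed,
            "missing_rate": self.missing_rate,
            "paired_slope": self.paired_slope,
            "paired_noise_sd": self.paired_noise_sd,
        }


@dataclass
class GeneratedScreen:
    data_path: Path
    label_path: Path
    truth_path: Path
    truth: SyntheticScreenTruth


def _fmt(value: float) -> str:
    return repr(float(value))


def generate_screen(truth: SyntheticScreenTruth, out_dir) -> GeneratedScreen:
    """Write data CSV (3 header rows), label CSV and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.seed)
    features = truth.feature_names()
    counts = truth.cell_counts()

    data_path = out / "screen_data.csv"
    with open(data_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["geneID", "imageID", "imageURL", "cellID"]
                        + features)
        writer.writerow(["Gene", "Image", "Image", "Cell"]
                        + ["Cell"] * len(features))
        writer.writerow(["ID", "ID", "URL", "ID"]
                        + ["NUMBER"] * len(features))
        cell_no = 0
        for gene in truth.gene_ids():
            shifts = np.array([truth.effect_sizes.get((gene, f), 0.0)
                               for f in features])
            means = np.asarray(truth.base_means) \
                + shifts * np.asarray(truth.base_sds)
            n = counts[gene]
            values = rng.normal(loc=means, scale=truth.base_sds,
                                size=(n, truth.n_features))
            if truth.paired_slope is not None:
                noise = rng.normal(0.0, truth.paired_noise_sd, size=n)
                values[:, -1] = truth.paired_slope * values[:, 0] + noise
            if truth.missing_rate > 0:
                mask = rng.random(values.shape) < truth.missing_rate
            else:
                mask = np.zeros(values.shape, dtype=bool)
            for i in range(n):
                cell_no += 1
                image_no = (i // CELLS_PER_IMAGE) + 1
                image_id = f"img_{gene}_{image_no:03d}"
                row = [gene, image_id,
                       URL_TEMPLATE.format(image_id=image_id),
                       f"c{cell_no:07d}"]
                row += ["" if mask[i, j] else _fmt(values[i, j])
                        for j in range(truth.n_features)]
                writer.writerow(row)

    label_path = out / "screen_labels.csv"
    hit_set = set(truth.hit_genes)
    with open(label_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["geneID", "hit"])
        for gene in truth.gene_ids():
            writer.writerow([gene, 1 if gene in hit_set else 0])

    truth_path = out / "screen_truth.json"
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump(truth.to_json_obj(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return GeneratedScreen(data_path=data_path, label_path=label_path,
                           truth_path=truth_path, truth=truth)


# --------------------------------------------------------------------------
# corrupted fixtures


@dataclass
class CorruptedFixture:
    """A screen with exactly one injected defect at a recorded coordinate.

    ``path`` points at the defective file (the data CSV, or the label CSV
    for the unknown-label-id variant); ``row``/``column`` are 1-based.
    """

    variant: str
    path: Path
    data_path: Path
    label_path: Path
    row: int
    column: int | None


def generate_corrupted(variant: str, seed: int = 0,
                       out_dir=".") -> CorruptedFixture:
    """Generate a small screen and inject one defect of ``variant``."""
    if variant not in CORRUPTION_VARIANTS:
        raise GenerationError(
            f"unknown corruption variant {variant!r}; "
            f"expected one of {CORRUPTION_VARIANTS}")
    out = Path(out_dir)
    truth = SyntheticScreenTruth.default(n_genes=5, cells_per_gene=4,
                                         n_features=2, n_hits=1, seed=seed)
    screen = generate_screen(truth, out)
    data_lines = screen.data_path.read_text(
        encoding="utf-8").splitlines(keepends=False)

    if variant == "missing-type-row":
        del data_lines[2]
        screen.data_path.write_text("\n".join(data_lines) + "\n",
                                    encoding="utf-8")
        return CorruptedFixture(variant, screen.data_path,
                                screen.data_path, screen.label_path,
                                row=3, column=None)
    if variant == "bad-number-cell":
        row, column = 7, 5  # data row, first NUMBER column (1-based)
        cells = data_lines[row - 1].split(",")
        cells[column - 1] = "abc"
        data_lines[row - 1] = ",".join(cells)
        screen.data_path.write_text("\n".join(data_lines) + "\n",
                                    encoding="utf-8")
        return CorruptedFixture(variant, screen.data_path,
                                screen.data_path, screen.label_path,
                                row=row, column=column)
    if variant == "ragged-row":
        row = 9
        cells = data_lines[row - 1].split(",")
        data_lines[row - 1] = ",".join(cells[:-1])
        screen.data_path.write_text("\n".join(data_lines) + "\n",
                                    encoding="utf-8")
        return CorruptedFixture(variant, screen.data_path,
                                screen.data_path, screen.label_path,
                                row=row, column=None)
    # unknown-label-id: one label row referencing a gene outside the screen
    label_lines = screen.label_path.read_text(
        encoding="utf-8").splitlines(keepends=False)
    label_lines.append("g9999,1")
    screen.label_path.write_text("\n".join(label_lines) + "\n",
                                 encoding="utf-8")
    return CorruptedFixture(variant, screen.label_path,
                            screen.data_path, screen.label_path,
                            row=len(label_lines), column=None)
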