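"""Command-line pipeline: simulate -> extract -> measure -> efa -> summarize
-> pca -> correlate -> physignal.

Each subcommand is a thin wrapper over the library, reading a flat TOML
config (any key overridable by flag) and writing tidy CSVs plus a JSON run
manifest (config echo, package version, output content hashes). All
randomness flows from the single config seed through named substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import tomllib
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import __version__, descriptors, efa, geometry, physig, stats, synthetic_data

logger = logging.getLogger("paveshape")
logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")


@dataclass
class RunConfig:
    """Flat configuration for every pipeline stage."""

    outdir: str = "paveshape_out"
    seed: int = 0
    # inputs (simulate fills these in itself)
    masks_dir: str | None = None
    outlines_csv: str | None = None
    leaves_csv: str | None = None
    metadata_csv: str | None = None
    newick: str | None = None
    # parameters
    microns_per_pixel: float = 1.0
    min_area_px: float = geometry.DEFAULT_MIN_AREA_PX
    cells_per_side: int = stats.DEFAULT_CELLS_PER_SIDE
    n_species_per_clade: int = 30
    resample_points: int = descriptors.RESAMPLE_POINTS
    n_harmonics: int = efa.DEFAULT_HARMONICS
    pca_standardize: bool = True
    moran_n_perm: int = physig.DEFAULT_N_PERM
    moran_alpha: float = physig.DEFAULT_ALPHA

    @classmethod
    def load(cls, path: str | None, **overrides) -> "RunConfig":
        data: dict = {}
        if path is not None:
            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise click.ClickException(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def substream(self, name: str) -> int:
        """Named derived seed, stable across runs (kept below 2^31)."""
        return (int(self.seed) * 1_000_003 + zlib.crc32(name.encode())) % (2**31 - 1)


def _outdir(cfg: RunConfig) -> Path:
    p = Path(cfg.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, index=False)
    manifest.setdefault("outputs", {})[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    logger.info("wrote %s (%d rows)", path, len(df))


def _finish(cfg: RunConfig, manifest: dict, stage: str) -> None:
    out = _outdir(cfg)
    manifest.update(stage=stage, version=__version__, config=asdict(cfg))
    with open(out / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _require(path: str | None, what: str) -> str:
    if path is None or not Path(path).exists():
        raise click.ClickException(f"missing required input: {what} ({path!r})")
    return path


def _load_metrics(cfg: RunConfig) -> pd.DataFrame:
    path = Path(cfg.outdir) / "cell_metrics.csv"
    if not path.exists():
        raise click.ClickException(f"no cell metrics at {path}; run `paveshape measure` first")
    return pd.read_csv(path)


def _load_summaries(cfg: RunConfig) -> pd.DataFrame:
    path = Path(cfg.outdir) / "species_summaries.csv"
    if not path.exists():
        raise click.ClickException(f"no summaries at {path}; run `paveshape summarize` first")
    return pd.read_csv(path)


_config_option = click.option("--config", "config_path", type=click.Path(exists=True), default=None)
_outdir_option = click.option("--outdir", default=None, help="output directory")
_seed_option = click.option("--seed", type=int, default=None)


@click.group()
def main() -> None:
    """Outline morphometrics of leaf pavement cells."""


@main.command()
@_config_option
@_outdir_option
@_seed_option
@click.option("--cells-per-side", type=int, default=None)
@click.option("--n-species-per-clade", type=int, default=None)
def simulate(config_path, outdir, seed, cells_per_side, n_species_per_clade) -> None:
    """Generate the shipped synthetic clade-structured dataset and its tree."""
    cfg = RunConfig.load(config_path, outdir=outdir, seed=seed, cells_per_side=cells_per_side,
                         n_species_per_clade=n_species_per_clade)
    out = _outdir(cfg)
    clades = [
        # dataclasses.replace on frozen CladeSpec to resize the default spec
        synthetic_data.CladeSpec(**{**asdict_clade(c), "n_species": cfg.n_species_per_clade})
        for c in synthetic_data.DEFAULT_CLADES
    ]
    ds = synthetic_data.make_dataset(clades, cells_per_side=cfg.cells_per_side,
                                     seed=cfg.substream("simulate"), n_points=cfg.resample_points)
    manifest: dict = {}
    frames = []
    for species, cell_id, side, outline in ds.cells:
        f = geometry.outlines_to_frame([outline], species=species, side=side)
        f["cell_id"] = cell_id
        frames.append(f)
    _write(pd.concat(frames, ignore_index=True)[geometry.OUTLINE_CSV_COLUMNS], out / "outlines.csv", manifest)
    _write(ds.leaves, out / "leaves.csv", manifest)
    _write(ds.meta, out / "metadata.csv", manifest)
    _write(ds.ground_truth, out / "ground_truth.csv", manifest)
    tree = synthetic_data.make_clade_tree(ds.meta, seed=cfg.substream("tree"))
    (out / "tree.nwk").write_text(tree.write_newick() + "\n")
    manifest.setdefault("outputs", {})["tree.nwk"] = hashlib.sha256((out / "tree.nwk").read_bytes()).hexdigest()
    _finish(cfg, manifest, "simulate")


def asdict_clade(c: synthetic_data.CladeSpec) -> dict:
    d = asdict(c)
    d["sides"] = tuple(d["sides"])
    return d


@main.command()
@_config_option
@_outdir_option
@click.option("--masks-dir", default=None, type=click.Path(exists=True))
@click.option("--microns-per-pixel", type=float, default=None)
def extract(config_path, outdir, masks_dir, microns_per_pixel) -> None:
    """Trace cell outlines from a directory of binary mask images.

    File names are parsed as <species>__<side>.<ext>; each connected
    component becomes one cell outline.
    """
    from PIL import Image

    cfg = RunConfig.load(config_path, outdir=outdir, masks_dir=masks_dir,
                         microns_per_pixel=microns_per_pixel)
    mdir = Path(_require(cfg.masks_dir, "masks_dir"))
    out = _outdir(cfg)
    manifest: dict = {}
    frames = []
    for img_path in sorted(mdir.glob("*.png")) + sorted(mdir.glob("*.tif")) + sorted(mdir.glob("*.tiff")):
        species, _, side = img_path.stem.partition("__")
        mask = np.asarray(Image.open(img_path))
        try:
            outlines = geometry.trace_outlines(
                mask, geometry.Scale(cfg.microns_per_pixel), min_area=cfg.min_area_px,
                label_prefix=img_path.stem,
            )
        except ValueError as exc:
            logger.error("skipping %s: %s", img_path.name, exc)
            continue
        kept = [o for o in outlines if not o.border_touching]
        logger.info("%s: %d outlines (%d border-touching excluded)",
                    img_path.name, len(kept), len(outlines) - len(kept))
        f = geometry.outlines_to_frame(kept, species=species, side=side or "adaxial")
        frames.append(f)
    if not frames:
        raise click.ClickException(f"no mask images found in {mdir}")
    _write(pd.concat(frames, ignore_index=True), out / "outlines.csv", manifest)
    _finish(cfg, manifest, "extract")


@main.command()
@_config_option
@_outdir_option
@click.option("--outlines-csv", default=None, type=click.Path(exists=True))
def measure(config_path, outdir, outlines_csv) -> None:
    """Resample each outline and compute the four shape descriptors."""
    cfg = RunConfig.load(config_path, outdir=outdir, outlines_csv=outlines_csv)
    out = _outdir(cfg)
    path = cfg.outlines_csv or str(out / "outlines.csv")
    records = geometry.frame_to_outlines(pd.read_csv(_require(path, "outlines_csv")))
    manifest: dict = {}
    rows, failures = [], 0
    for species, cell_id, side, outline in records:
        try:
            m = descriptors.measure(outline, n_points=cfg.resample_points)
        except ValueError as exc:
            logger.error("skipping %s/%s: %s", species, cell_id, exc)
            failures += 1
            continue
        rows.append({"species": species, "cell_id": cell_id, "side": side,
                     "area_um2": m.area, "perimeter_um": m.perimeter, "solidity": m.solidity,
                     "aspect_ratio": m.aspect_ratio, "circularity": m.circularity})
    df = pd.DataFrame(rows)
    if len(df) >= 4:
        for metric, col in [("solidity", "quartile_S"), ("aspect_ratio", "quartile_AR")]:
            df[col] = descriptors.quartile_classify(df[metric], metric=metric).classes
    else:
        logger.warning("fewer than 4 outlines; skipping quartile classification")
    _write(df, out / "cell_metrics.csv", manifest)
    manifest["n_failed_outlines"] = failures
    _finish(cfg, manifest, "measure")


@main.command(name="efa")
@_config_option
@_outdir_option
@click.option("--outlines-csv", default=None, type=click.Path(exists=True))
@click.option("--n-harmonics", type=int, default=None)
def efa_cmd(config_path, outdir, outlines_csv, n_harmonics) -> None:
    """Normalized elliptic Fourier coefficients for every cell outline."""
    cfg = RunConfig.load(config_path, outdir=outdir, outlines_csv=outlines_csv, n_harmonics=n_harmonics)
    out = _outdir(cfg)
    path = cfg.outlines_csv or str(out / "outlines.csv")
    records = geometry.frame_to_outlines(pd.read_csv(_require(path, "outlines_csv")))
    manifest: dict = {}
    frames = []
    for species, cell_id, side, outline in records:
        o = efa.align_longest_radius(geometry.resample(outline, cfg.resample_points))
        coeffs = efa.efa_normalize(efa.efa_forward(o, cfg.n_harmonics))
        frames.append(efa.coefficients_to_frame(coeffs, species=species, cell_id=cell_id, side=side))
    _write(pd.concat(frames, ignore_index=True), out / "efa_coefficients.csv", manifest)
    _finish(cfg, manifest, "efa")


@main.command()
@_config_option
@_outdir_option
@_seed_option
def summarize(config_path, outdir, seed) -> None:
    """Species/side aggregation plus dataset medians, ranges and quartiles."""
    cfg = RunConfig.load(config_path, outdir=outdir, seed=seed)
    out = _outdir(cfg)
    cells = _load_metrics(cfg)
    leaves = pd.read_csv(out / "leaves.csv") if (out / "leaves.csv").exists() else None
    meta = pd.read_csv(out / "metadata.csv") if (out / "metadata.csv").exists() else None
    manifest: dict = {}
    summaries = stats.summarize_species(cells, leaves, meta, cells_per_side=cfg.cells_per_side,
                                        seed=cfg.substream("subsample"))
    _write(summaries, out / "species_summaries.csv", manifest)
    manifest["dataset_medians_species"] = stats.dataset_medians(summaries)
    manifest["dataset_medians_cells"] = stats.dataset_medians(summaries, cells=cells, over="cells")
    _finish(cfg, manifest, "summarize")


@main.command()
@_config_option
@_outdir_option
@click.option("--no-standardize", "standardize_off", is_flag=True, default=False)
def pca(config_path, outdir, standardize_off) -> None:
    """PCA of the all-cells descriptor table."""
    cfg = RunConfig.load(config_path, outdir=outdir)
    if standardize_off:
        cfg.pca_standardize = False
    out = _outdir(cfg)
    cells = _load_metrics(cfg)
    manifest: dict = {}
    res = stats.pca_descriptors(cells, standardize=cfg.pca_standardize)
    _write(res.loadings.reset_index(names="descriptor"), out / "pca_loadings.csv", manifest)
    _write(pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(res.variance_explained))],
                         "variance_fraction": res.variance_explained}),
           out / "pca_variance.csv", manifest)
    _write(pd.DataFrame(res.scores, columns=[f"PC{i+1}" for i in range(res.scores.shape[1])]),
           out / "pca_scores.csv", manifest)
    manifest["pc1_pc2_variance_pct"] = float(100.0 * res.variance_explained[:2].sum())
    _finish(cfg, manifest, "pca")


@main.command()
@_config_option
@_outdir_option
def correlate(config_path, outdir) -> None:
    """Leaf-AR vs cell-AR correlations and the adaxial-abaxial comparison."""
    cfg = RunConfig.load(config_path, outdir=outdir)
    out = _outdir(cfg)
    summaries = _load_summaries(cfg)
    manifest: dict = {}
    sd = stats.side_difference(summaries)
    _write(sd.per_species, out / "side_difference.csv", manifest)
    manifest["side_difference"] = {"n_both_sides": sd.n_both_sides, "n_positive": sd.n_positive,
                                   "fraction_positive": sd.fraction_positive}
    rows = []
    subsets = {"all": None, "fern_gymnosperm_monocot": ["fern", "gymnosperm", "monocot"],
               "eudicot_EDA": ["eudicot", "EDA"]}
    for name, clades in subsets.items():
        try:
            r = stats.leaf_cell_correlation(summaries, clades)
        except ValueError as exc:
            logger.warning("subset %s skipped: %s", name, exc)
            continue
        rows.append({"subset": name, "rho": r.rho, "n": r.n, "p_value": r.p_value})
    _write(pd.DataFrame(rows), out / "leaf_cell_correlation.csv", manifest)
    _finish(cfg, manifest, "correlate")


@main.command()
@_config_option
@_outdir_option
@_seed_option
@click.option("--newick", default=None, type=click.Path(exists=True))
@click.option("--trait", "trait_name", default="mean_solidity",
              type=click.Choice(["mean_solidity", "mean_aspect_ratio"]))
def physignal(config_path, outdir, seed, newick, trait_name) -> None:
    """Local Moran's I hotspot test of a species-mean trait on the phylogeny."""
    cfg = RunConfig.load(config_path, outdir=outdir, seed=seed, newick=newick)
    out = _outdir(cfg)
    tree_path = cfg.newick or str(out / "tree.nwk")
    tree = physig.read_newick(Path(_require(tree_path, "newick tree")).read_text())
    summaries = _load_summaries(cfg)
    trait = dict(zip(summaries["species"], summaries[trait_name]))
    trait = {k: v for k, v in trait.items() if np.isfinite(v)}
    W = physig.proximity_matrix(tree)
    res = physig.local_moran(trait, W, n_perm=cfg.moran_n_perm,
                             seed=cfg.substream("moran"), alpha=cfg.moran_alpha)
    manifest: dict = {}
    _write(res.to_frame(), out / f"moran_{trait_name}.csv", manifest)
    manifest["moran"] = {"trait": trait_name, "global_I": res.global_I, "expected_I": res.expected_I,
                         "p_global": res.p_global, "n_hotspots": int(res.hotspot.sum()),
                         "n_hotspots_bh": int(res.hotspot_bh.sum()),
                         "method": W.method, "n_permutations": res.n_permutations, "alpha": res.alpha}
    _finish(cfg, manifest, "physignal")


if __name__ == "__main__":
    main()
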