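"""End-to-end analyses chaining the library modules, with reproducible reports.

Each ``run_*`` function takes a plain config dict, performs one of the named
analyses and writes TSV tables plus a JSON summary.  Every output carries a
header with the tool version, a hash of the config and the seed, and every
stochastic step is driven by the mandatory ``seed`` entry, so re-running a
config reproduces its outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

import perichrom
from perichrom import (
    consensus_union,
    line_profile,
    peripheral_enrichment,
    permutation_test,
    read_bed,
    read_chrom_sizes,
    shell_distribution_test,
    shell_partition,
    subtelomeric_windows,
    subtract_control,
    write_bed,
)
from perichrom.geometry import NucleusMask, assign_to_shells
from perichrom.spots import SpotSet, count_in_masks, read_spots_tsv

__all__ = [
    "config_hash",
    "report_header",
    "run_subtelomere_analysis",
    "run_position_analysis",
    "run_profile_analysis",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a config dict (sorted-key JSON, sha1)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def report_header(config: dict) -> list[str]:
    return [
        f"perichrom {perichrom.__version__}",
        f"config_hash {config_hash(config)}",
        f"seed {config.get('seed')}",
    ]


def _write_tsv(path: Path, header: list[str], columns: list[str], rows) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def _write_json(path: Path, config: dict, payload: dict) -> None:
    out = {
        "tool": f"perichrom {perichrom.__version__}",
        "config_hash": config_hash(config),
        "seed": config.get("seed"),
        **payload,
    }
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2)


# ---------------------------------------------------------------------------
# Subtelomere enrichment
# ---------------------------------------------------------------------------

def run_subtelomere_analysis(config: dict) -> dict:
    """Consensus binding sites and subtelomeric enrichment with permutation p.

    Config keys: ``chrom_sizes``, ``peaks`` (one path) or ``rep1``/``rep2``
    (two replicate paths, combined by consensus), optional ``control`` (peak
    set subtracted at peak level), ``bed_format``, ``window_bp``,
    ``membership``, ``n_perm``, ``seed``, ``min_overlap_bp``, ``out_dir``.
    Writes ``consensus.bed`` (when two replicates are given),
    ``subtelomere_enrichment.tsv`` and ``subtelomere_enrichment.json``.
    """
    genome = read_chrom_sizes(config["chrom_sizes"])
    fmt = config.get("bed_format", "bed3")
    min_ov = int(config.get("min_overlap_bp", 1))
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    if "rep1" in config and "rep2" in config:
        rep1 = read_bed(config["rep1"], genome, fmt)
        rep2 = read_bed(config["rep2"], genome, fmt)
        if "control" in config and config["control"]:
            ctrl = read_bed(config["control"], genome, fmt)
            rep1 = subtract_control(rep1, ctrl, min_ov)
            rep2 = subtract_control(rep2, ctrl, min_ov)
        peaks = consensus_union(rep1, rep2, min_ov, config.get("consensus_mode", "union"))
    else:
        peaks = read_bed(config["peaks"], genome, fmt)
        if "control" in config and config["control"]:
            ctrl = read_bed(config["control"], genome, fmt)
            peaks = subtract_control(peaks, ctrl, min_ov)

    if len(peaks) == 0:
        raise ValueError("no peaks left after input processing")

    windows = subtelomeric_windows(genome, int(config.get("window_bp", 500_000)))
    res = permutation_test(
        peaks,
        windows,
        genome,
        n_perm=int(config.get("n_perm", 1000)),
        seed=int(config["seed"]),
        membership=config.get("membership", "midpoint"),
    )

    header = report_header(config)
    if "rep1" in config and "rep2" in config:
        write_bed(peaks, out_dir / "consensus.bed", header=header)
    _write_tsv(
        out_dir / "subtelomere_enrichment.tsv",
        header,
        ["n_obs", "n_total", "f_obs", "f_exp", "fold", "p_perm", "p_binom", "n_perm"],
        [[res.n_obs, res.n_total, f"{res.f_obs:.6g}", f"{res.f_exp:.6g}",
          f"{res.fold:.6g}", f"{res.p_perm:.6g}", f"{res.p_binom:.6g}", res.n_perm]],
    )
    summary = {
        "n_consensus_sites": len(peaks),
        "n_obs": res.n_obs,
        "n_total": res.n_total,
        "f_obs": res.f_obs,
        "f_exp": res.f_exp,
        "fold": res.fold,
        "p_perm": res.p_perm,
        "p_binom": res.p_binom,
        "n_perm": res.n_perm,
    }
    _write_json(out_dir / "subtelomere_enrichment.json", config, summary)
    return summary


# ---------------------------------------------------------------------------
# Shell positioning
# ---------------------------------------------------------------------------

def _load_mask(path: str) -> NucleusMask:
    import tifffile

    return NucleusMask(np.asarray(tifffile.imread(path)).astype(np.int32))


def _condition_shell_counts(
    mask: NucleusMask, spots: SpotSet, n_shells: int
) -> tuple[np.ndarray, int, list[tuple[int, int, int]]]:
    """Accumulate per-shell counts over all nuclei of one mask image.

    Returns (counts, n_outside, rows) where rows are (nucleus, shell, count).
    """
    counts = np.zeros(n_shells, dtype=int)
    per_nucleus, outside = count_in_masks(spots, mask)
    rows = []
    pts = spots.points()
    for lab in sorted(per_nucleus):
        region = mask.region(lab)
        part = shell_partition(region, n_shells)
        nuc_pts = [
            (x, y)
            for (x, y) in pts
            if 0 <= int(round(y)) < region.shape[0]
            and 0 <= int(round(x)) < region.shape[1]
            and region[int(round(y)), int(round(x))]
        ]
        c, out = assign_to_shells(nuc_pts, part)
        counts += c
        outside += out
        for s in range(n_shells):
            rows.append((lab, s + 1, int(c[s])))
    return counts, outside, rows


def run_position_analysis(config: dict) -> dict:
    """Radial (shell) positioning of spots, optionally comparing two conditions.

    Config: ``conditions`` — mapping of condition name to dict with ``mask``
    (label TIFF) and ``spots`` (TSV) paths; ``n_shells`` (default 5);
    ``seed``; ``out_dir``.  Writes per-condition shell counts
    (``shell_counts.tsv``) and, with exactly two conditions, per-shell Fisher
    and overall chi-square p-values in ``position_analysis.json``.
    """
    n_shells = int(config.get("n_shells", 5))
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    header = report_header(config)

    cond_counts: dict[str, np.ndarray] = {}
    rows = []
    for name, spec in config["conditions"].items():
        mask = _load_mask(spec["mask"])
        spots = read_spots_tsv(spec["spots"])
        counts, outside, nuc_rows = _condition_shell_counts(mask, spots, n_shells)
        cond_counts[name] = counts
        for lab, shell, c in nuc_rows:
            rows.append([name, lab, shell, c])
        rows.append([name, "all", "outside", outside])
    _write_tsv(
        out_dir / "shell_counts.tsv",
        header,
        ["condition", "nucleus", "shell", "count"],
        rows,
    )
    summary: dict = {
        "n_shells": n_shells,
        "counts": {k: v.tolist() for k, v in cond_counts.items()},
    }
    if len(cond_counts) == 2:
        (na, ca), (nb, cb) = cond_counts.items()
        test = shell_distribution_test(ca, cb)
        summary["comparison"] = {
            "conditions": [na, nb],
            "per_shell_fisher_p": test["per_shell_p"].tolist(),
            "chi2_p": test["chi2_p"],
        }
    _write_json(out_dir / "position_analysis.json", config, summary)
    return summary


# ---------------------------------------------------------------------------
# Peripheral-enrichment profiles
# ---------------------------------------------------------------------------

def run_profile_analysis(config: dict) -> dict:
    """Per-nucleus line-profile peripheral enrichment, with a group test.

    Config: ``conditions`` — mapping of condition name to dict with
    ``image`` (signal TIFF) and ``mask`` (label TIFF); ``edge_fraction``,
    ``line_width_px``, ``seed``, ``out_dir``.  Nuclei whose plateau is flat
    or too small are excluded and counted.  With two conditions a
    Mann-Whitney U test on the per-nucleus ratios is reported.
    """
    import tifffile
    from scipy import stats

    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    header = report_header(config)
    edge_fraction = float(config.get("edge_fraction", 0.25))
    line_width = int(config.get("line_width_px", 1))

    rows = []
    per_cond: dict[str, list[float]] = {}
    n_failed: dict[str, int] = {}
    for name, spec in config["conditions"].items():
        img = np.asarray(tifffile.imread(spec["image"])).astype(float)
        mask = _load_mask(spec["mask"])
        ratios = []
        failed = 0
        for lab in range(1, mask.n_nuclei + 1):
            try:
                prof = line_profile(
                    img, mask.region(lab), line_width_px=line_width
                )
                pe = peripheral_enrichment(prof, edge_fraction)
            except ValueError:
                failed += 1
                continue
            ratios.append(pe.ratio)
            rows.append(
                [name, lab, f"{pe.max1:.6g}", f"{pe.max2:.6g}",
                 f"{pe.plateau_median:.6g}", f"{pe.ratio:.6g}"]
            )
        per_cond[name] = ratios
        n_failed[name] = failed
    _write_tsv(
        out_dir / "profile_enrichment.tsv",
        header,
        ["condition", "nucleus", "max1", "max2", "plateau_median", "ratio"],
        rows,
    )
    summary: dict = {
        "medians": {k: (float(np.median(v)) if v else None) for k, v in per_cond.items()},
        "n_nuclei": {k: len(v) for k, v in per_cond.items()},
        "n_failed": n_failed,
    }
    vals = [v for v in per_cond.values() if v]
    if len(per_cond) == 2 and len(vals) == 2 and min(len(v) for v in vals) >= 2:
        u, p = stats.mannwhitneyu(vals[0], vals[1], alternative="two-sided")
        summary["mannwhitney_p"] = float(p)
    _write_json(out_dir / "profile_analysis.json", config, summary)
    return summary
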