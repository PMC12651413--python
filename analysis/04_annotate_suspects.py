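#!/usr/bin/env python
"""Suspect-screening annotation demo on the simulated study.

Builds a suspect database wired to ten designated features (plus decoys),
screens every feature at 5 ppm / 0.2 min / 0.01 Da tolerances, and writes
the annotation evidence table under results/analysis/annotation/.
"""

from pathlib import Path

from tomarker.annotate import annotate_features, annotations_to_frame, best_per_feature
from tomarker.io import read_feature_table, write_mgf
from tomarker.simulate import simulate_suspect_db

IN = Path("results/analysis/sim")
OUT = Path("results/analysis/annotation")
SEED = 20260918


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = read_feature_table(
        IN / "intensities.csv", IN / "injections.csv", IN / "features.csv"
    )
    suspects, spectra, expected = simulate_suspect_db(
        table, n_true=10, n_decoy=40, mz_jitter_ppm=2.0,
        fragment_overlap=0.8, rt_known_fraction=0.6, seed=SEED,
    )
    write_mgf(spectra, OUT / "feature_ms2.mgf")
    anns = annotate_features(table, suspects, spectra=spectra)
    frame = annotations_to_frame(anns)
    frame.to_csv(OUT / "annotations.tsv", sep="\t", index=False)

    best = best_per_feature(anns)
    levels = {}
    for a in best:
        levels[a.level] = levels.get(a.level, 0) + 1
    recalled = sum(
        1 for name, fid in expected.items()
        if any(a.suspect == name and a.feature_id == fid and a.level != "none"
               for a in best)
    )
    decoy_hits = sum(1 for a in best if a.suspect.startswith("decoy_"))
    print(f"screened {table.n_features} features against {len(suspects)} suspects")
    print(f"  best-per-pair annotations by level: {levels}")
    print(f"  planted suspects recovered: {recalled}/{len(expected)}; decoy hits: {decoy_hits}")
    print("  (standards with shifted RT surface as 'derivative of ...' at L3)")


if __name__ == "__main__":
    main()
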