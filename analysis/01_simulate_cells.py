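"""Simulate the two cell populations and record their ground truth.

Generates test-scale mesoangioblast-like and myotube-like populations
(object counts drawn around 30 ± 12 and 167 ± 71 respectively; the myotube
preset is sized so its expected total mitochondrial volume is ~12x the
mesoangioblast's) and writes the exact planted per-cell quantities to
results/ground_truth_cells.csv. Scripts 02+ re-simulate the same seeds, so
this table is the reference every downstream recovery is judged against.
"""

from pathlib import Path

import pandas as pd

from mitoquant import mesoangioblast_preset, myotube_preset, simulate_population

SEED = 2026
N_MESO, N_MYO = 6, 3

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for label, preset, n_cells in (
        ("mesoangioblast", mesoangioblast_preset, N_MESO),
        ("myotube", myotube_preset, N_MYO),
    ):
        params, variability = preset()
        cells = simulate_population(params, n_cells, variability, seed=SEED)
        for i, (_, truth) in enumerate(cells):
            rows.append(
                {
                    "group": label,
                    "cell_id": f"{label}_{i}",
                    "n_objects": truth.n_objects,
                    "total_mt_volume_um3": truth.total_mito_volume_um3,
                    "nucleus_volume_um3": truth.nucleus_volume_um3,
                    "cell_volume_um3": truth.cell_volume_um3,
                    "cytoplasm_volume_um3": truth.cell_volume_um3 - truth.nucleus_volume_um3,
                }
            )
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "ground_truth_cells.csv", index=False)

    by_group = df.groupby("group")["total_mt_volume_um3"].mean()
    ratio = by_group["myotube"] / by_group["mesoangioblast"]
    print(df.to_string(index=False))
    print(
        f"\nplanted mean mt volume: mesoangioblast {by_group['mesoangioblast']:.0f} µm³, "
        f"myotube {by_group['myotube']:.0f} µm³ (ratio {ratio:.1f}x)"
    )


if __name__ == "__main__":
    main()
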