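"""Double-angle DA plots with centroids and 95% confidence ellipses.

Renders the before/after-optimization DA clouds for the automated
keratometer and TCRP 4.0 mm pupil/zone, and reports the ellipse areas --
after optimization the clouds centre on the origin and the ellipses
shrink.

Reads results/cohort.csv; writes results/figures/.
"""

from pathlib import Path

from astigvec.cohort import read_cohort
from astigvec.doubleangle import mean_confidence_ellipse, render_da_plot
from astigvec.optimize import fit_optimization, optimized_da
from astigvec.pipeline import eye_da_table

ROOT = Path(__file__).resolve().parents[1] / "results"
PAIR = ("auto_ka", "tcrp_4.0_pupil_zone")


def main() -> None:
    records = read_cohort(ROOT / "cohort.csv")
    figdir = ROOT / "figures"
    figdir.mkdir(exist_ok=True)
    for m in PAIR:
        before = eye_da_table(records, m)
        after = optimized_da(records, fit_optimization(records, m))
        render_da_plot(before, figdir / f"da_{m}_before.svg", title=f"DA before optimization: {m}")
        render_da_plot(after, figdir / f"da_{m}_after.svg", title=f"DA after optimization: {m}")
        area_b = mean_confidence_ellipse(before).area
        area_a = mean_confidence_ellipse(after).area
        print(f"{m}: 95% mean-ellipse area {area_b:.4f} -> {area_a:.4f} D^2")
    print(f"wrote {figdir}")


if __name__ == "__main__":
    main()
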