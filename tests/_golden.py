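"""Golden-file scenarios: five seeded fixture-to-SVG CLI renders.

Used by the golden regression test and by scripts/make_goldens.py to
(re)generate the committed reference SVGs under tests/golden/.
"""

from pathlib import Path

from click.testing import CliRunner

from specplot.cli import main

GOLDEN_DIR = Path(__file__).parent / "golden"

# (name, fixture kind, fixture seed, fixture params, render args)
SCENARIOS = [
    (
        "ms", "ms-peaks", 7, [],
        ["--type", "ms", "--legend", "--labels", "--title", "MS demo"],
    ),
    (
        "nmr1d", "nmr-trace", 11, ["--n-points", "20000"],
        ["--type", "nmr1d", "--xmin", "3", "--xmax", "9", "--legend"],
    ),
    (
        "ir", "ir-trace", 13, [],
        ["--type", "ir", "--title", "IR demo"],
    ),
    (
        "nmr2d", "nmr2d-points", 17, [],
        ["--type", "nmr2d"],
    ),
    (
        "timeseries", "nmr-trace", 19, ["--n-points", "2000"],
        ["--type", "timeseries"],
    ),
]


def render_scenarios(workdir: Path) -> dict[str, bytes]:
    """Run every golden scenario through the CLI; return name -> SVG bytes."""
    runner = CliRunner()
    out: dict[str, bytes] = {}
    for name, kind, seed, fparams, rargs in SCENARIOS:
        fxdir = workdir / f"fx-{name}"
        res = runner.invoke(
            main,
            ["fixtures", "--kind", kind, "--out-dir", str(fxdir), "--seed", str(seed)]
            + fparams,
            catch_exceptions=False,
        )
        assert res.exit_code == 0, res.output
        (infile,) = [p for p in fxdir.iterdir() if p.suffix == ".json"]
        svg_path = workdir / f"{name}.svg"
        res = runner.invoke(
            main,
            ["render", "--in", str(infile), "--out", str(svg_path)] + rargs,
            catch_exceptions=False,
        )
        assert res.exit_code == 0, res.output
        out[name] = svg_path.read_bytes()
    return out
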