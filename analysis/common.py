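"""Shared plumbing for the numbered analysis drivers.

The raw synthetic dataset (voltage-step sweep CSVs are ~200 kB each) lives
under scratch/run-<seed>/ and is regenerated on demand; the drivers write
only small derived tables under results/.
"""

from __future__ import annotations

from pathlib import Path

from click.testing import CliRunner

from gatkin.cli import main as gatkin_cli

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
DEFAULT_SEED = 1


def dataset_dir(seed: int = DEFAULT_SEED) -> Path:
    """Return the synthetic dataset directory, generating it if absent."""
    out = SCRATCH / f"run-{seed}"
    if not (out / "manifest.csv").exists():
        res = CliRunner().invoke(gatkin_cli, ["simulate", "--seed", str(seed),
                                              "--out", str(out)])
        if res.exit_code != 0:
            raise RuntimeError(f"dataset generation failed: {res.output}")
    RESULTS.mkdir(exist_ok=True)
    return out
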