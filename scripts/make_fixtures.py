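"""Regenerate the packaged fixture signals bit-exactly.

Run from the repository root:

    python scripts/make_fixtures.py
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

from pacsense import fixtures, generate_test_signal, simulate_contrast_experiment

OUTDIR = Path(__file__).resolve().parent.parent / "src" / "pacsense" / "fixtures"


def main() -> None:
    from pacsense.io import write_signal

    for name, cfg in fixtures.TEST_SIGNAL_CONFIGS.items():
        sig = generate_test_signal(cfg)
        sig.label = name
        write_signal(sig, OUTDIR / f"{name}.txt", header=asdict(cfg))
        print(f"wrote {name}.txt ({len(sig)} samples)")

    for group in ("AP_GNP", "NP", "water"):
        exp = simulate_contrast_experiment(
            fixtures.CONTRAST_CONFIG,
            group=group,
            enhancement_factor=fixtures.CONTRAST_FACTOR,
            seed=fixtures.CONTRAST_SEED,
        )
        for stage, sig in (("pre", exp.pre), ("post", exp.post)):
            name = f"contrast_{group.lower()}_{stage}"
            sig.label = name
            write_signal(
                sig,
                OUTDIR / f"{name}.txt",
                header={
                    "group": group,
                    "stage": stage,
                    "seed": fixtures.CONTRAST_SEED,
                    "enhancement_factor": exp.enhancement_factor,
                },
            )
            print(f"wrote {name}.txt ({len(sig)} samples)")


if __name__ == "__main__":
    main()
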