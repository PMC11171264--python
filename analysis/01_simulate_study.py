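"""Simulate the demo cohort: one mIHC slide per patient plus outcomes.

Writes the study (cell tables, annotations, truth sidecars, clinical
table) under results/demo/study/.
"""

from pathlib import Path

import yaml

from melaband import synthetic

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "demo" / "study"


def main() -> None:
    cfg = yaml.safe_load((ROOT / "analysis" / "demo_config.yaml").read_text())
    sim = dict(cfg["simulation"])
    sim.setdefault("seed", cfg.get("seed", 0))
    study = synthetic.generate_study(synthetic.StudySimConfig(**sim))
    synthetic.write_study(study, OUT)
    n_cells = sum(len(c) for c in study.cell_tables.values())
    n_events = int(study.clinical["event"].sum())
    print(
        f"wrote {len(study.annotations)} slides ({n_cells} cells) to {OUT}; "
        f"{n_events}/{len(study.clinical)} patients with an event"
    )


if __name__ == "__main__":
    main()
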