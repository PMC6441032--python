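"""Write the run summary and the partition-shares figure.

The figure shows, per sensitivity metric, the share of explained deviance
attributed to SDM, GCM and RCP at each TSS retention threshold; the text
summary mirrors it as data.
"""

from pathlib import Path

from bioscen.pipeline import ExperimentConfig, run_stage

ROOT = Path(__file__).resolve().parents[1]
OUTDIR = ROOT / "results" / "demo"


def main() -> None:
    cfg = ExperimentConfig.from_yaml(ROOT / "configs" / "demo.yaml")
    run_stage("report", cfg, OUTDIR)
    print((OUTDIR / "report.txt").read_text())
    print(f"figure: {OUTDIR / 'partition_shares.png'}")


if __name__ == "__main__":
    main()
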