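"""DNase-protection qPCR analysis of spontaneously released phage.

Free DNA in a culture supernatant (from lysed cells) is degraded by DNase,
while DNA packaged inside a phage capsid is protected.  Comparing Cq values
between DNase-treated and untreated supernatant aliquots therefore reads
out encapsidation: the smaller the treated-minus-untreated difference
(ΔCq), the larger the protected fraction.  Normalizing each target's ΔCq
against a chromosomal housekeeper (here the small ribosomal protein gene
*s10p*) with the 2^-ΔΔCq transform yields a fold-change measure of phage
release; a target is called detected when its treated signal stays above
the assay floor set by its no-template control (NTC), and the housekeeper
itself should fall below its NTC when bacterial DNA is fully degraded.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

DEFAULT_CQ_CAP = 40.0  # matches a 40-cycle protocol
DEFAULT_HOUSEKEEPER = "s10p"

#: tokens marking a non-amplifying replicate in input tables
NO_AMP_TOKENS = {"", "na", "nan", "noamp", "no-amp", "undetermined", "none"}


def aggregate_cq(replicates: Sequence, cq_cap: float = DEFAULT_CQ_CAP) -> float:
    """Mean Cq of a replicate set, imputing non-amplifying wells at the cap.

    Replicates may be numbers or ``None``/NaN (non-amplifying, imputed at
    ``cq_cap`` — the cycle count of the protocol).
    """
    if len(replicates) == 0:
        raise ValueError("replicate list must be non-empty")
    values = []
    for r in replicates:
        if r is None or (isinstance(r, float) and math.isnan(r)):
            values.append(cq_cap)
        else:
            values.append(float(r))
    return sum(values) / len(values)


def delta_cq(treated_mean: float, untreated_mean: float) -> float:
    """ΔCq = treated − untreated (DNase raises Cq for degradable targets)."""
    return treated_mean - untreated_mean


def fold_change(delta_cq_target: float, delta_cq_housekeeper: float) -> float:
    """2^−ΔΔCq fold change of a target relative to the housekeeper."""
    return 2.0 ** -(delta_cq_target - delta_cq_housekeeper)


def detection_call(
    treated_mean: float, ntc_cq: Optional[float], margin: float = 0.0
) -> bool:
    """Detected iff the treated signal clears the NTC floor by ``margin`` cycles."""
    if ntc_cq is None:
        return False
    return treated_mean < ntc_cq - margin


@dataclass
class QpcrTarget:
    """Replicate Cq sets for one primer pair."""

    name: str
    treated_cq: list
    untreated_cq: list
    ntc_cq: Optional[float] = None

    def __post_init__(self):
        if not self.treated_cq or not self.untreated_cq:
            raise ValueError(f"target {self.name}: need >=1 replicate per condition")


@dataclass
class QpcrResult:
    target: str
    treated_mean: float
    untreated_mean: float
    delta_cq: float
    ddcq: float
    fold_change: float
    detected: bool
    fully_degraded: bool = False  # housekeeper only: treated signal at/under NTC


@dataclass
class QpcrPanel:
    """A panel of qPCR targets with a designated housekeeper."""

    targets: dict
    housekeeper: str = DEFAULT_HOUSEKEEPER
    cq_cap: float = DEFAULT_CQ_CAP
    ntc_margin: float = 0.0

    def __post_init__(self):
        if self.housekeeper not in self.targets:
            raise ValueError(f"housekeeper {self.housekeeper!r} missing from panel")
        for t in self.targets.values():
            for cq in list(t.treated_cq) + list(t.untreated_cq):
                if cq is not None and not (isinstance(cq, float) and math.isnan(cq)):
                    if not 0.0 < float(cq) <= self.cq_cap:
                        raise ValueError(
                            f"target {t.name}: Cq {cq} outside (0, {self.cq_cap}]"
                        )

    def analyze(self) -> dict:
        """Per-target means, ΔCq, ΔΔCq, fold change and detection calls."""
        hk = self.targets[self.housekeeper]
        hk_delta = delta_cq(
            aggregate_cq(hk.treated_cq, self.cq_cap),
            aggregate_cq(hk.untreated_cq, self.cq_cap),
        )
        results: dict[str, QpcrResult] = {}
        for name, t in self.targets.items():
            treated = aggregate_cq(t.treated_cq, self.cq_cap)
            untreated = aggregate_cq(t.untreated_cq, self.cq_cap)
            d = delta_cq(treated, untreated)
            results[name] = QpcrResult(
                target=name,
                treated_mean=treated,
                untreated_mean=untreated,
                delta_cq=d,
                ddcq=d - hk_delta,
                fold_change=fold_change(d, hk_delta),
                detected=detection_call(treated, t.ntc_cq, self.ntc_margin),
                fully_degraded=(
                    name == self.housekeeper
                    and t.ntc_cq is not None
                    and treated >= t.ntc_cq
                ),
            )
        return results

    def release_ranking(self) -> list[str]:
        """Phage targets ranked by fold change, most released first."""
        results = self.analyze()
        phages = [n for n in results if n != self.housekeeper]
        return sorted(phages, key=lambda n: -results[n].fold_change)


# ---------------------------------------------------------------------------
# IO


def read_cq_csv(
    path,
    housekeeper: str = DEFAULT_HOUSEKEEPER,
    cq_cap: float = DEFAULT_CQ_CAP,
    ntc_margin: float = 0.0,
) -> QpcrPanel:
    """Read a replicate table ``target,condition,replicate,cq`` into a panel.

    ``condition`` is one of treated/untreated/ntc; an empty or
    'undetermined' Cq marks a non-amplifying well.
    """
    targets: dict[str, dict] = {}
    with Path(path).open() as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or row[0] == "target" or row[0].startswith("#"):
                continue
            name, condition = row[0], row[1].strip().lower()
            raw = row[3].strip() if len(row) > 3 else ""
            cq = None if raw.lower() in NO_AMP_TOKENS else float(raw)
            slot = targets.setdefault(
                name, {"treated": [], "untreated": [], "ntc": []}
            )
            if condition not in slot:
                raise ValueError(f"{Path(path).name}:{lineno}: bad condition {row[1]!r}")
            slot[condition].append(cq)
    panel_targets = {}
    for name, slot in targets.items():
        ntc_values = [c for c in slot["ntc"] if c is not None]
        panel_targets[name] = QpcrTarget(
            name=name,
            treated_cq=slot["treated"],
            untreated_cq=slot["untreated"],
            ntc_cq=aggregate_cq(ntc_values, cq_cap) if ntc_values else None,
        )
    return QpcrPanel(
        targets=panel_targets,
        housekeeper=housekeeper,
        cq_cap=cq_cap,
        ntc_margin=ntc_margin,
    )


def write_cq_csv(panel: QpcrPanel, path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["target", "condition", "replicate", "cq"])
        for name, t in panel.targets.items():
            for i, cq in enumerate(t.treated_cq, start=1):
                w.writerow([name, "treated", str(i), "" if cq is None else repr(cq)])
            for i, cq in enumerate(t.untreated_cq, start=1):
                w.writerow([name, "untreated", str(i), "" if cq is None else repr(cq)])
            if t.ntc_cq is not None:
                w.writerow([name, "ntc", "1", repr(t.ntc_cq)])


def write_qpcr_report(results: dict, path) -> None:
    """Write per-target results as TSV."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "target",
                "treated_mean_cq",
                "untreated_mean_cq",
                "delta_cq",
                "ddcq",
                "fold_change",
                "detected",
                "fully_degraded",
            ]
        )
        for name, r in results.items():
            w.writerow(
                [
                    name,
                    f"{r.treated_mean:.3f}",
                    f"{r.untreated_mean:.3f}",
                    f"{r.delta_cq:.3f}",
                    f"{r.ddcq:.3f}",
                    f"{r.fold_change:.4g}",
                    str(r.detected),
                    str(r.fully_degraded),
                ]
            )
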