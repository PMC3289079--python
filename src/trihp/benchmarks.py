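"""The eight-sequence triangular-lattice benchmark suite and run driver.

The registry stores each benchmark in its published power notation
together with the best energies reported for it by several methods:
a simple GA (SGA) and hybrid GA (HGA) from earlier work, the
elite-reproduction GA (ERS-GA), a tabu search (TS), and the
hill-climbing hybrid (HHGA). Two published tables disagree on sequence
2 (-13 for the ERS-GA comparison vs -17 for the HHGA/TS comparison);
both values are kept under their own method keys and not reconciled.
The published HHGA mean for sequence 6 is printed with its sign dropped
(34.1); it is stored here as -34.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Dict, Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .ga import GAConfig, RunResult, run_ersga
from .local_search import run_hhga
from .model import folds_to_symbols, parse_hp_notation

__all__ = ["BenchmarkEntry", "BENCHMARKS", "BenchmarkReport", "run_benchmark"]


@dataclass(frozen=True)
class BenchmarkEntry:
    id: int
    notation: str
    expected_length: int
    #: published best energy per method; absent entries were not reported
    reference_energies: Mapping[str, int] = field(default_factory=dict)
    #: published mean best energy over 30 runs, per method
    reference_means: Mapping[str, float] = field(default_factory=dict)

    @cached_property
    def sequence(self) -> str:
        seq = parse_hp_notation(self.notation)
        if len(seq) != self.expected_length:
            raise AssertionError(
                f"benchmark {self.id}: expanded length {len(seq)} != "
                f"registered length {self.expected_length}"
            )
        return seq


BENCHMARKS: Dict[int, BenchmarkEntry] = {
    e.id: e
    for e in [
        BenchmarkEntry(1, "(HP)^2PH(HP)^2(PH)^2HP(PH)^2", 20,
                       {"SGA": -11, "HGA": -15, "ERS-GA": -15, "TS": -15, "HHGA": -15},
                       {"ERS-GA": -12.5, "HHGA": -14.73}),
        BenchmarkEntry(2, "H^2P^2(HP^2)^6H^2", 24,
                       {"SGA": -10, "HGA": -13, "ERS-GA": -13, "TS": -17, "HHGA": -17},
                       {"ERS-GA": -10.2, "HHGA": -14.93}),
        BenchmarkEntry(3, "P^2HP^2(H^2P^4)^3H^2", 25,
                       {"SGA": -10, "HGA": -10, "ERS-GA": -12, "TS": -12, "HHGA": -12},
                       {"ERS-GA": -8.47, "HHGA": -11.57}),
        BenchmarkEntry(4, "P(P^2H^2)^2P^5H^5(H^2P^2)^2P^2H(HP^2)^2", 36,
                       {"SGA": -16, "HGA": -19, "ERS-GA": -20, "TS": -24, "HHGA": -23},
                       {"ERS-GA": -16.17, "HHGA": -21.27}),
        BenchmarkEntry(5, "P^2H(P^2H^2)^2P^5H^10P^6(H^2P^2)^2HP^2H^5", 48,
                       {"SGA": -26, "HGA": -32, "ERS-GA": -32, "TS": -40, "HHGA": -41},
                       {"ERS-GA": -28.13, "HHGA": -37.3}),
        BenchmarkEntry(6, "H^2(PH)^3PH^4PH(P^3H)^2P^4(HP^3)^2HPH^4(PH)^3PH^2", 50,
                       {"SGA": -21, "HGA": -23, "ERS-GA": -30, "HHGA": -38},
                       {"ERS-GA": -25.3, "HHGA": -34.1}),
        BenchmarkEntry(7, "P(PH^3)^2H^5P^3H^10PHP^3H^12P^4H^6PH^2PHP", 60,
                       {"SGA": -40, "HGA": -46, "ERS-GA": -55, "TS": -70, "HHGA": -66},
                       {"ERS-GA": -49.43, "HHGA": -61.83}),
        BenchmarkEntry(8, "H^12(PH)^2((P^2H^2)^2P^2H)^3(PH)^2H^11", 64,
                       {"SGA": -33, "HGA": -46, "ERS-GA": -47, "TS": -50, "HHGA": -63},
                       {"ERS-GA": -42.37, "HHGA": -56.53}),
    ]
}

_ALGORITHMS = {"ersga": run_ersga, "hhga": run_hhga}
_REF_KEY = {"ersga": "ERS-GA", "hhga": "HHGA"}


@dataclass
class BenchmarkReport:
    """Per-run rows, per-benchmark summary, and the best conformations."""

    runs: pd.DataFrame
    summary: pd.DataFrame
    best_conformations: Dict[int, np.ndarray]

    def write_tsv(self, runs_path, summary_path=None) -> None:
        self.runs.to_csv(runs_path, sep="\t", index=False)
        if summary_path is not None:
            self.summary.to_csv(summary_path, sep="\t", index=False)


def run_benchmark(
    ids: Iterable[int],
    algorithm: str = "hhga",
    cfg: Optional[GAConfig] = None,
    progress: bool = False,
) -> BenchmarkReport:
    """Run ``cfg.runs`` independent seeded runs per selected benchmark.

    Run i of a benchmark uses seed ``cfg.seed + i`` (i = 0..runs-1), so
    ``cfg.seed = 1`` reproduces the convention of seeding repeated runs
    1, 2, ..., runs. The summary compares the best energy against the
    published value for the chosen algorithm, where one exists.
    """
    if algorithm not in _ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; use 'ersga' or 'hhga'")
    if cfg is None:
        cfg = GAConfig()
    runner = _ALGORITHMS[algorithm]

    run_rows = []
    summary_rows = []
    best_confs: Dict[int, np.ndarray] = {}
    for bid in ids:
        entry = BENCHMARKS[int(bid)]
        seq = entry.sequence
        best: Optional[RunResult] = None
        energies = []
        for i in range(cfg.runs):
            seed = cfg.seed + i
            res = runner(seq, cfg.with_(seed=seed))
            energies.append(res.best_energy)
            run_rows.append({
                "seq_id": entry.id,
                "run_index": i,
                "seed": seed,
                "best_energy": res.best_energy,
                "generations": res.generations_run,
                "feasible": res.feasible,
                "fold_string": folds_to_symbols(res.best_conf) if res.feasible else "",
            })
            if res.feasible and (best is None or res.best_energy < best.best_energy):
                best = res
            if progress:
                print(f"seq {entry.id} run {i}: best {res.best_energy}", flush=True)
        ref = entry.reference_energies.get(_REF_KEY[algorithm])
        if best is not None:
            best_confs[entry.id] = best.best_conf
        if best is None:
            flag = "no feasible solution"
        elif ref is None:
            flag = "no reference"
        elif best.best_energy < ref:
            flag = "better than reference"
        elif best.best_energy == ref:
            flag = "matched reference"
        else:
            flag = "worse than reference"
        feasible_e = [e for e in energies if e is not None]
        summary_rows.append({
            "seq_id": entry.id,
            "length": entry.expected_length,
            "runs": cfg.runs,
            "mean_energy": float(np.mean(feasible_e)) if feasible_e else None,
            "best_energy": best.best_energy if best is not None else None,
            "reference_best": ref,
            "vs_reference": flag,
        })
    return BenchmarkReport(
        pd.DataFrame(run_rows), pd.DataFrame(summary_rows), best_confs
    )
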