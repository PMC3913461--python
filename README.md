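# roreview

Automated review of cardiac-arrest resuscitation episodes from minimal
event annotations and defibrillator logs.

## The problem

During out-of-hospital cardiac arrest an AED records an event log (power-on
time, each delivered shock with energy and impedance, mode switches) while
trained reviewers annotate the ECG with rhythm transitions and the
compression signal with compression start/stop times. EMS registries then
abstract dozens of per-shock review variables from this material by hand —
a slow process with substantial inter-observer variability. `roreview`
automates the abstraction: it builds a compact state-sequence
representation of the episode from the minimal annotation set, derives
every registry variable from it by explicit rules, and audits the derived
database against a manually abstracted one.

It is a library for resuscitation researchers and registry maintainers,
with a thin `rorev` command-line layer for batch use.

## The representation and the rules

An episode over $[t_s, t_e)$ is modeled as two run-length encoded label
timelines built from transition events:

* **therapy domain** $S_T$ over states $\{C, H, D\}$ — compression
  sequences, hands-off intervals, defibrillations — built from paired
  `c1/c2` and `d1/d2` events, hands-off by default;
* **response domain** $S_R$ over rhythm states
  $\{VF, VT, AS, PE, PR, UN\}$ — each lower-case transition event
  (`vf`, `as`, …) opens its state until the next transition.

The combined representation $S_C$ is the join: its transition times are
the union of both domains' transition times over the intersection of their
spans, and each state's label concatenates therapy and rhythm (e.g. `DVF`
= shock delivered during ventricular fibrillation). Intervals are
half-open, so every instant maps to exactly one state.

For every shock the episode is segmented into pre-/post-shock windows
(bounded by neighbouring shocks or the begin/end-of-episode markers) and
the review variables are derived by querying the representation: first/last
compression before the shock, VF-onset and ROSC times after it (with the
persistent-VF sentinel `99:99:99` when the rhythm stays VF through the
10/30/60 s checks), rhythm codes at 10/30/60/120 s after the shock with a
±5 s discretion window, VF/organized-rhythm/ROSC occurrence before the
next shock, stacked-shock run sizes, device mode, CPR presence, energy and
impedance. The audit codes every cell of a manual-vs-derived comparison as
correct (1), wrong (2, time deviation above the 1 s tolerance) or missing
(3, a sentinel code on either side).

## Worked example

```python
import roreview as rv
from roreview.core import Event

therapy = rv.build_therapy_sequence(
    [Event("c1", 805.2), Event("c2", 887.2), Event("d1", 903.3),
     Event("d2", 908.3), Event("c1", 938.8), Event("c2", 1062.0)],
    span_start=740.8, span_end=1062.0)
response = rv.build_response_sequence(
    [Event("vf", 793.6), Event("pe", 908.3), Event("vf", 944.0)],
    span_end=1062.0)
for iv in rv.combine(therapy, response):
    print(f"{iv.start:.1f}–{iv.end:.1f}: {iv.label}")
```

prints the seven combined states

```
793.6–805.2: HVF
805.2–887.2: CVF
887.2–903.3: HVF
903.3–908.3: DVF
908.3–938.8: HPE
938.8–944.0: CPE
944.0–1062.0: CVF
```

— the rhythm is VF throughout except a short PEA spell after the shock;
compressions pause for a hands-off interval around the 5-second
defibrillation at 903.3 s. The combined span starts at 793.6 s because the
response domain is undefined before its first annotation.

Runnable narrative scripts live in `examples/`: building and rendering the
representation (`worked_example.py`), deriving per-shock review variables
from a simulated episode (`derive_review_variables.py`), and auditing a
derived database against a corrupted manual one (`audit_demo.py`). The
same capabilities are available from the shell:

```bash
rorev simulate --seed 1 --episodes 5 -o bundles/
rorev derive bundles/sim1_000_log.jsonl bundles/sim1_000_annotations.csv -o derived.csv
rorev compare bundles/sim1_000_truth.csv derived.csv
```

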