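# Methods

## The state-sequence model

A resuscitation episode is represented as two label timelines over elapsed
seconds since device power-on. The therapy domain takes values in
{C, H, D} (compressions, hands-off, defibrillation); the response domain
in {VF, VT, AS, PE, PR, UN} (ventricular fibrillation, ventricular
tachycardia, asystole, pulseless electrical activity, pulse-giving rhythm,
unknown). Both are built from minimal transition annotations: `c1/c2` and
`d1/d2` pairs delimit compressions and shocks, and each lower-case rhythm
code marks the transition *into* the corresponding state, which persists
until the next transition. The combined representation concatenates the
two labels (therapy first) on the union of transition times over the
intersection of the two spans.

Key representational choices:

* **Half-open intervals.** Adjacent states share a boundary instant; with
  closed intervals a point query at a transition would be ambiguous.
  Every query, window and comparison in the package uses `[start, end)`.
* **Undefined response before the first annotation.** The rhythm timeline
  begins at its first event rather than being padded with UN; UN appears
  only when explicitly annotated. Consequently the combined sequence
  starts at the later of the two domain starts. A window over which the
  response domain is undefined yields the no-data sentinel rather than a
  guessed rhythm.
* **Therapy is hands-off by default.** Uncovered time between power-on
  and the first annotation, or between annotated activities, is H. This
  is the only defensible neutral state: the device is on and nothing is
  documented as happening to the patient.
* **Strictness over tolerance.** Unpaired or overlapping therapy events
  and simultaneous rhythm transitions are rejected with the offending
  time named, not tie-broken: they indicate corrupt annotations, and any
  silent repair would poison every derived variable downstream.
* Times are stored at millisecond resolution and rendered at 0.1 s; the
  plain-text episode rendering round-trips exactly for boundaries on the
  0.1 s grid, which both the annotation dialect and the simulator use.

## Wall-clock reconciliation

The device log carries elapsed milliseconds; the manual registry stores
absolute hour/minute/second triplets. Conversion runs through a serial
day number — fractional days since January 1 of year 0 in the proleptic
Gregorian calendar (January 1 of year 1 = 367) — anchored at the logged
power-on timestamp, which is assumed synchronized with local time; no
drift correction is attempted. Derived times are rounded half-up to whole
seconds, since the registry stores whole seconds and the audit tolerance
absorbs sub-second effects. Sentinel triplets (`99:99:99` unknown,
`88:88:88` no CPR administered, `66:66:66` no data available) and the
flagged blank literals `00:00:00`/`12:00:00` form a total classification:
every triplet is exactly one of valid, one of the three sentinels, or a
flagged literal. `66:66:66` is emitted when a derivation window has an
undefined response domain; its attested use elsewhere is thin, so it is
treated as the generic no-data code.

## The review rules

Per shock, windows are `[previous shock, shock)` and `[shock, next
shock)`, with begin/end-of-episode markers at the extremes; the windows
tile the episode exactly. A state interval beginning at the shock instant
belongs to the post-shock window (half-open convention).

* **First/last compression**: start of the first C and end of the last C
  in the pre-shock window (the end of the last C equals the start of the
  final hands-off interval before the shock); `88:88:88` when there is no
  C. A first compression coinciding with the recording start is flagged
  "ongoing at start".
* **Rhythm checkpoints** r10/r30/r60/r120 read the post-shock response
  restriction at `shock + shock_end_offset + Δ`, with two discretion
  rules inside a ±5 s window: a transition into VF inside the window
  overrides the reading to VF, and an unknown state at the checkpoint
  falls back to the last known rhythm provided it was still present
  inside the window. Checkpoints beyond the recorded domain (recording
  ended, or the next shock reached first) read unknown (9). Codes:
  asystole 1, VF 2, VT 3, organized 4 (PE and PR both — PR is
  distinguished only in the ROSC variables), unknown 9.
* **Persistent VF**: when the pre-shock rhythm and the 10/30/60 s
  checkpoints are all VF, VF onset is coded `99:99:99` ("no onset, the
  patient remained in VF"). The 120 s check deliberately does not
  participate. An unknown rhythm at any participating position blocks
  the persistent coding. When no transition into VF occurs at all,
  `99:99:99` is likewise emitted: the registry's alternative (a blank
  cell) has no faithful triplet encoding, and both cases are sentinel
  (missing) for audit purposes.
* **vfpr / orgpr** (VF / organized rhythm before the next shock): yes if
  such an interval intersects the window strictly after the shock; *no*
  only when the whole window is covered by known (non-UN) rhythm;
  otherwise unknown — one cannot assert absence over an unannotated or
  unknown span. **rosc** answers yes iff a PR interval intersects the
  window, no otherwise, unknown only when the response domain is
  undefined there: the representation cannot testify to pulses that were
  never annotated as PR.
* **Stacked shocks** (`shks`): consecutive shocks with no compression
  interval between them form a run; every shock in a run of size n
  reports n. Maximal-run semantics were chosen over incremental-counter
  readings of the procedure because the variable's registry definition
  ("number of shocks without intervening CPR", 1 = no stacked shocks) is
  a property of the run, not of a scan order.
* **mode** follows the latest mode-switch log entry before the shock
  (advisory when none — AEDs power up in advisory mode); **cpr** is yes
  iff any compression interval intersects the pre-shock window, with a
  reconciliation convention: a manual row whose first- and
  last-compression times are both coded unknown is interpreted as CPR
  present. Energy and impedance are copied verbatim from the log
  (999 when absent).

`shock_end_offset_s` defaults to 0 s — checkpoints are offsets from shock
delivery, which reproduces the published walkthrough (shock at 198 s,
asystole read at 208 s, organized rhythm at 258 s). The alternative
convention that the shock ends 3 s after delivery is first-class
configuration (`ReviewConfig(shock_end_offset_s=3.0)`), as are the
checkpoint offsets, the ±5 s half-width and the audit tolerance.

## The audit coding

Each compared cell is correct (1), wrong (2) or missing (3). Time
variables: missing when *either* side is a sentinel or flagged literal;
otherwise correct iff the absolute deviation is within the tolerance
(default 1 s), computed modulo 24 h so a midnight rollover compares as
seconds, not hours. Categorical codes are correct only when identical;
energy and impedance are integers compared with zero allowed deviation.
Rows are aligned by (episode id, shock number), never by file order —
a missing shock in one database must surface as an alignment error, not
as silently shifted comparisons. Summaries report per-variable counts,
the match rate correct/(correct+wrong) with missing excluded from the
denominator, and the share of missing cells where both sides used the
same missing code. Raising the tolerance can only move cells from wrong
to correct, so correct counts are monotone in the tolerance — asserted as
a property on corrupted synthetic data.

## The synthetic cohort

No deposited episode data exists, so validation uses a seeded simulator.
Each episode draws: a duration uniform on 600–1800 s; a rhythm timeline
starting 20–60 s after power-on from a semi-Markov chain (initial state
VF with probability 0.7, else AS/PE/VT; exponential dwell times with
means of 40–150 s per state, floor 6 s; a 5% chance per transition of an
unknown spell); compression sequences from 30–90 s after power-on with
exponential durations (mean 60 s, floor 10 s) separated by hands-off
intervals (mean 12 s, floor 4 s); 1–5 shocks of 5 s placed only inside
hands-off gaps with ≥1 s margins, stacked in pairs with probability 0.15;
energies from {150, 200, 360} J and impedances uniform on 50–120 Ω; a 20%
chance of a manual-mode switch; and with probability 0.6 per shock an
extra rhythm transition 2–8 s after delivery (the only coupling between
therapy and rhythm). These values were chosen once as representative of
out-of-hospital VF arrest practice — shock counts, duty cycles and energy
menus follow common protocol ranges — and are all exposed on `SimParams`.

Ground truth is computed analytically from the raw generated segment
lists by plain scans, sharing only the code tables with the review
engine; the recovery test (derive from the emitted files, audit against
truth) is therefore a genuine dual-route check. What the simulator does
*not* emulate: annotation noise and inter-observer disagreement, device
clock desynchronization, truncated or corrupted logs, rhythm dynamics
conditioned on CPR quality, and the skewed missingness patterns of real
registries (missingness is injected uniformly at random by `corrupt`).
Passing recovery tests therefore demonstrates that the rules are
internally consistent and invertible on clean annotations — not that the
engine matches human abstractors on real data, which requires a manual
registry to compare against.

## Numerical choices and problem sizes

Contiguity uses a 1 ns slack; interval construction reuses exact
boundary floats so no drift accumulates. Combination labels are read at
piece midpoints, immune to boundary dust. Coincident transitions in both
domains collapse to a single combined transition; zero-length pieces are
discarded. The dense-grid oracle tests compare at 0.01 s spacing against
an independent linear interval-mask classifier. Standard test scales:
1,000 random sequence pairs for the merge oracle, 200 episodes for
cohort recovery, 30 for sentinel detection, 20 for tolerance
monotonicity — sizes at which every property is exercised thousands of
times per run while the whole suite stays fast enough to run on every
change.

## Known limitations

* Rhythm and compression annotations must exist; detecting them from ECG
  or impedance waveforms is out of scope.
* Vendor binary log formats are not parsed; the JSONL/CSV dialects
  defined in `episode_io` are the ingestion contract and adapters must
  produce them.
* ROSC inference is only as good as the PR annotations: un-annotated
  pulses are invisible to the representation.
* The combined representation joins exactly two domains; ventilation or
  circulation channels would need an n-way join.
* Concordance rates against a real manually-abstracted registry cannot be
  computed here; the synthetic audit measures internal consistency only.
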