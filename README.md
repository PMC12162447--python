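# iotalearn

Rate-based, information-theoretic analysis of associative learning from
time-stamped behavioral event records.

## The problem

In Pavlovian and operant experiments, what a subject learns is not a
probability of reinforcement but a temporal *contingency*: how much a
predictor (a tone, a response, the chamber itself) tells it about when
the next reinforcement will arrive. `iotalearn` implements the
rate-based model of that computation. Everything is extracted from a
**temporal map** — a two-column record of time stamps and event codes —
by counting events and cumulating durations:

- **Informativeness** `ι = λ_R|CS / λ_R|C`: the ratio of the
  reinforcement rate conditional on a predictor to the contextual rate.
  Unitless and time-scale invariant.
- **Communicated information** `ΔH = ln ι`: the reduction in entropy of
  the wait-time distribution (exponential entropy `H = 1 − ln λ`).
- **Evidence** `nDKL = n_e · (ln ι + 1/ι − 1)` with effective sample
  size `n_e = n_R|CS / (1 + n_R|CS/n_R|C)`: computable from a single
  reinforcement, distributed gamma(.5, 1) under no association, so it
  yields exact p-values and odds.
- **Learning Rate Law** `RtoAcq = k/(ι − 1)`: reinforcements before
  conditioned responding appears, with `k` the informativeness giving
  one-shot acquisition.
- **Credit assignment** `λ̂ = P⁻¹λ`: attributed rates solved from
  observed conditional rates through the temporal-probability matrix of
  duration ratios.
- **Change detection** (Eq.-by-event nDKL profiles): online detection of
  rate/probability changes, which turns extinction and the scalar
  partial-reinforcement extinction effect into change-point statistics.
- **Dwell-Time Equation** `μ_D|I = 1/(k·λ_R|J)`: time allocation on
  concurrent VI schedules, from which the Matching Law and the
  Belke–Gibbon revealed-preference results follow.

Seeded protocol simulators (delay, trace, truly-random control, VI
single/concurrent, and a closed-loop virtual subject) generate every
input the analyses consume.

Intended users: quantitative behavioral scientists and modelers who
want these statistics computed reproducibly from event logs, and a
reference implementation of the model's laws to test against data.

## Worked example

After 6 hours (21,600 s) in a chamber, a 1-s noise sounds and a shock
follows at its offset (`examples/one_shot_association.py`):

```text
CS rate          1/s   (1 shock in 1 s)
contextual rate  4.63e-05/s   (1 shock in 21600 s)
informativeness  21600
association      14.4 bits
nDKL             4.5 nats   (effective n = 0.5)
p value          0.0027
odds against coincidence  365:1
```

The noise communicates 14.4 bits about the timing of the next shock,
and a sample of one already puts the odds hundreds to one against
coincidence — which is why one-shot learning is possible when the
temporal relation is informative enough.

Each script in `examples/` exercises one capability the same way:
credit assignment for the contingency-not-pairing experiment, the
Learning Rate Law across protocols, the scalar partial-reinforcement
extinction effect, matching/revealed preference, and the closed-loop
virtual subject.

A thin CLI wraps the same library calls:

```bash
iotalearn analyze --events session.csv --cs cs:noise --reinf reinf:shock
iotalearn predict dwell --vi1 40 --vi2 80
iotalearn simulate pree --p .75,.5,.33,.1 --reps 16 --seed 1
```

Event files are plain text (`time_s,event` header, `#` comments, one
`time,code` row per event; a `# stamps=duration` header switches to
interevent-interval stamps).

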