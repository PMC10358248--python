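# oncoclaims

Line-of-therapy construction, treatment-episode segmentation and monthly
direct-medical-cost estimation for chemotherapy cohorts in administrative
claims — built around the setting of systemic chemotherapy for pancreatic
cancer in Japanese DPC-hospital claims, with a ground-truth-bearing
synthetic-claims simulator so every stage can be verified offline.

## The problem

Real-world treatment patterns and costs of pancreatic-cancer chemotherapy
must be reconstructed from administrative claims: there is no progression
field, no "line of therapy" field, and no episode labels — only dated
diagnoses, prescriptions and priced claim lines. The pipeline implements a
prescription-defined reconstruction:

1. **Cohort selection.** Patients with (i) a definitive pancreatic-cancer
   diagnosis (ICD-10 C25x); (ii) any claim strictly more than 28 days
   before that first confirmed diagnosis (lookback, screening out
   mid-treatment transfers); (iii) no surgery/radiotherapy on or after the
   diagnosis; (iv) an indicated anticancer prescription within 60 days
   (inclusive) of the diagnosis; (v) diagnosis on or after 2015-01-01.
   Criteria run in flow-diagram order; the first failure is the recorded
   exclusion reason.
2. **Regimen classification.** A line is anchored at its first qualifying
   prescription (first line: initiated within 180 days of diagnosis);
   its components are every pancreatic-indicated anticancer drug first
   administered within a 28-day combination window. Labels: nab-paclitaxel
   ⇒ **GnP**; else ≥2 FOLFIRINOX components (oxaliplatin, irinotecan,
   fluorouracil, folinate) ⇒ **FFX**; gemcitabine alone ⇒ **GEM**; S-1
   alone ⇒ **S1**; anything else (incl. gemcitabine+erlotinib) ⇒ **other**.
3. **Episode segmentation.** 1stPFS runs from the index prescription to
   the treatment end date (oral drugs extend past the last fill by
   ⌊quantity / standard daily dose⌋ days; capped at last follow-up). A
   *switch* is the first prescription of a non-component indicated drug;
   restarting any subset of the first-line drugs — after any gap — is the
   same line, never a switch. Switchers get 1stPD (1stPFS end → switch)
   and 2ndPFS; non-switchers get TC (1stPFS end → last follow-up). OS runs
   from index to death or last follow-up.
4. **Cost aggregation.** Claim-line costs (JPY) are attributed to 30-day
   half-open months anchored at each episode start — only full windows
   count, at most six per episode — and split into six resource categories
   by the two-digit clinical identification code (administration 10–19,
   medicines 20–39, procedures 40–59, examinations 60–79, hospitalization
   90–99, other 80–89). Summaries are in USD at 114.59 JPY/USD; category
   shares cover the first three months of first-line treatment; cumulative
   per-episode totals (including OS) are reported unwindowed.

The **synthetic-claims simulator** (`oncoclaims.simulate`) emulates this
data-generating process — regimen mixture, cycle-dated prescriptions,
restart gaps, switches, death/censoring, category-structured lognormal
monthly costs, and planted eligibility violations — and emits per-patient
ground truth (verdicts, labels, boundaries, monthly cell costs), enabling
exact end-to-end recovery tests against commercial-database structure
without the commercial data.

## Worked example

```bash
python examples/05_monthly_costs.py
```

simulates 400 patients and prints, among other rows:

```
label episode_kind  month   N  mean   sd  min  median   max
  GnP         PFS1      1 133 11404 2267 7642   11037 19788
  GnP         PFS1      2 102  7285 1381 4489    7193 11984
  GnP         PFS1      3  82  7101 1461 4484    7077 11070
   S1         PFS1      6  22  1256  213  865    1188  1739
```

Each row is one cost month of first-line treatment: `N` patients whose
episode still covers a full 30-day window (shrinking as treatment ends),
with USD summary statistics of their monthly totals — first months run
highest (admission-heavy treatment starts) and GnP is the costliest
regimen, S-1 the cheapest, as configured in the generator. The category
shares table that follows shows medicines and hospitalization dominating
the intensive regimens, with each row summing to 100%.

Other examples cover simulation (`01`), cohort attrition (`02`), regimen
labels (`03`), episode chains (`04`) and the full pipeline with report
files (`06`). A thin CLI wraps the same functions:

```bash
onco generate --out data/ --seed 1 --n 500
onco run --data data/ --out reports/
```

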