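# Default operational codebook for classifying obstetric hospitalizations in
# SIH/SUS claims: obstetric-stay detection, reason for hospitalization,
# discharge type, and the 11 severe-maternal-morbidity criteria (7 diagnoses +
# 4 procedures drawn from the WHO severe-morbidity criterion list).
#
# ICD-10 entries: 1-3 character entries are prefixes (match any subcategory),
# 4-character entries are exact codes, "A to B" expands to the prefix range.
# Procedure entries are 10-digit SIGTAP codes, printed with dots/hyphen.
version: 1

# Diagnosis fields of the reduced (one-row-per-AIH) table scanned for ICD
# evidence. Real extracts differ by layout version; this list is configuration.
diagnosis_fields:
  - diag_primary
  - diag_secondary
  - diag_sec_1
  - diag_sec_2
  - diag_sec_3
  - diag_sec_4
  - diag_sec_5
  - diag_sec_6
  - diag_sec_7
  - diag_sec_8
  - diag_sec_9
  - diag_associated
  - diag_notification
  - diag_death

obstetric:
  # Chapter O in any configured diagnosis field, OR primary procedure below.
  icd: ["O"]
  procedures:
    - 02.01.01.001-1
    - 02.11.04.001-0
    - 02.11.04.006-1
    - 03.10.01.001-2
    - 03.10.01.002-0
    - 03.10.01.003-9
    - 03.10.01.004-7
    - 03.10.01.005-5
    - 03.03.10.001-0
    - 03.03.10.002-8
    - 03.03.10.003-6
    - 03.03.10.004-4
    - 03.03.10.005-2
    - 04.09.06.001-1
    - 04.09.06.005-4
    - 04.09.06.007-0
    - 04.11.01.001-8
    - 04.11.01.002-6
    - 04.11.01.003-4
    - 04.11.01.004-2
    - 04.11.01.005-0
    - 04.11.01.007-7
    - 04.11.01.008-5
    - 04.11.02.001-3
    - 04.11.02.002-1
    - 04.11.02.003-0
    - 04.11.02.004-8
    - 04.17.01.002-8
    - 04.17.01.001-0
    - 04.17.01.003-6

# Reason for hospitalization, evaluated on the FIRST admission record of the
# episode of care, in this precedence order. The pregnancy-complication row is
# also the catch-all: a primary ICD belonging to none of the four categories
# counts as a pregnancy complication, provided the procedure performed is not
# a delivery procedure (a delivery procedure always classifies as delivery).
reason:
  abortion:
    primary_icd: ["O00 to O08"]
  delivery:
    # Source material prints "032 to 036"; read as O32-O36 (typographic loss
    # of the letter; 032 is not an ICD-10 code).
    primary_icd: ["O32 to O36", "O60 to O69", "O75", "O80 to O84", "P95"]
    procedures:
      - 03.10.01.001-2
      - 03.10.01.003-9
      - 03.10.01.004-7
      - 03.10.01.005-5
      - 04.11.01.002-6
      - 04.11.01.003-4
      - 04.11.01.004-2
  pregnancy_complication:
    primary_icd: ["O10 to O28", "O30", "O31", "O40 to O48"]
    procedures: ["03.03.10.004-4"]
    catch_all: true
  puerperium_complication:
    primary_icd: ["O70 to O73", "O85 to O94"]
    procedures: ["03.03.10.001-0"]

# Discharge type: billing reason of the LAST admission record of the episode.
discharge:
  routine: ["1", "6.1", "6.2", "6.3", "6.4"]
  administrative: ["5"]
  continuing_stay: ["2"]
  death: ["4", "6.5", "6.6", "6.7"]
  transfer: ["3"]
  blank: [""]

# The 11 severe-morbidity criteria. ICD evidence may sit in any configured
# diagnosis field of any record in the episode; procedure evidence may come
# from the primary-procedure field or from any professional act. The ICU
# criterion additionally counts ICU stay-days > 0 (the UTI_MES_TO variable).
criteria:
  severe_preeclampsia:
    icd: [O141]
  eclampsia:
    icd: [O150, O151, O152, O159]
    procedures: ["03.03.10.002-8"]
  hellp_syndrome:
    icd: [O142]
  abruptio_placentae:
    icd: [O450, O458, O459]
  hemorrhage:
    icd: [O720, O721, O722, O723, O031, O036, O041, O046, O051, O056,
          O061, O066, O071, O076, O081]
  uterine_rupture:
    icd: [O710, O711]
  ectopic_pregnancy:
    icd: [O000, O001, O002, O008, O009]
    procedures: ["04.11.02.004-8"]
  hysterectomy:
    icd: [O822]   # cesarean-hysterectomy delivery code, kept as printed
    procedures:
      - 04.11.02.003-0
      - 04.09.06.010-0
      - 04.09.06.011-9
      - 04.09.06.012-7
      - 04.09.06.013-5
  laparotomy:
    procedures: ["04.07.04.016-1"]
  transfusion:
    icd: [Z513]
    procedures:
      - 03.06.02.006-8
      - 03.06.02.007-6
      - 03.06.02.008-4
      - 03.06.02.009-2
      - 03.06.02.010-6
      - 03.06.02.011-4
      - 03.06.02.012-2
      - 03.06.02.013-0
      - 03.06.02.014-9
  icu:
    procedures:
      - 08.02.01.010-5
      - 08.02.01.008-3
      - 08.02.01.009-1
      - 08.02.01.029-6
      - 08.02.01.031-8
    uses_icu_days: true
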