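group	vendor	pattern
low_quality	GE	Poor data quality, interpretation may be adversely affected
low_quality	GE	Acquisition hardware fault prevents reliable analysis, carefully check ECG record before interpreting
low_quality	GE	Baseline wander
low_quality	GE	Current undetermined rhythm precludes rhythm comparison, needs review
low_quality	GE	Electrode noise
low_quality	GE	Muscle tremor
low_quality	GE	Poor data quality
low_quality	GE	Poor data quality in current ECG precludes serial comparison
low_quality	Philips	All 12 leads are missing
low_quality	Philips	Artifact in lead(s)
low_quality	Philips	Artifact in lead(s) and baseline wander in lead(s)
low_quality	Philips	Baseline wander in lead(s)
low_quality	Philips	Incomplete analysis due to missing data in precordial lead(s)
low_quality	Philips	Missing lead(s)
low_quality	Philips	Missing lead(s) and partial lead(s)
low_quality	Philips	Poor-quality data—please repeat ECG!
arm_leads_reversed	GE	Suspect arm lead reversal, interpretation assumes no reversal
arm_leads_reversed	GE	Arm lead reversal
arm_leads_reversed	Philips	Left arm and left leg electrode reversal
arm_leads_reversed	Philips	Probable extremity electrode reversal
arm_leads_reversed	Philips	Right and left arm electrode reversal
arm_leads_reversed	Philips	Right arm and left leg electrode reversal
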