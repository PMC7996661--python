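# Health and social care occupation labels that must never be attributed to
# the patient. Normalized labels, one per line, lowercase.
psychiatrist
doctor
surgeon
nurse
psychiatric nurse
midwife
paramedic
therapist
psychotherapist
occupational therapist
physiotherapist
psychologist
counsellor
social worker
support worker
key worker
care coordinator
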