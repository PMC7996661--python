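mother
father
mum
dad
brother
sister
wife
husband
partner
son
daughter
uncle
aunt
grandmother
grandfather
cousin
stepfather
stepmother
nephew
niece
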