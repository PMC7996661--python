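# Occupation titles deliberately absent from the shipped gazetteer, used by
# the synthetic-corpus generator to emit out-of-lexicon mentions that only a
# trained sequence model can recover from context.
panel beater
dog groomer
locksmith
glazier
upholsterer
beekeeper
toolmaker
signwriter
stonemason
fishmonger
blacksmith
cobbler
milliner
thatcher
wheelwright
saddler
chandler
ropemaker
clockmaker
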