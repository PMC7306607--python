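taxon,affix,throw,reach,drag-roll,bait,contain,scratch,prop-climb,insert-probe,drop,pound,club,absorb,wipe,jab-stab,hang,symbolize,cut,wave-shake,dig,block,pry,aquatic,primate,bird,rank
insects,0,1,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0,class
arachnids,0,0,0,0,0,1,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,class
crustaceans,0,0,0,2,0,1,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0,1,0,0,class
gastropods,0,0,0,0,0,2,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,1,0,0,class
cephalopods,0,0,2,1,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,1,1,0,1,0,0,class
echinoderms,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0,phylum
fish,0,0,0,0,0,1,0,0,0,1,0,0,0,0,0,0,0,0,0,1,0,0,1,0,0,class
amphibians,0,0,2,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0,class
reptiles,0,0,0,1,0,2,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,class
birds,0,1,1,0,1,2,0,0,1,1,0,0,2,2,1,0,0,0,0,1,1,1,0,0,1,class
marsupials,0,2,0,1,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,infraclass
rodents,0,2,0,1,0,1,0,0,0,0,0,0,0,0,0,0,0,0,1,1,1,0,0,0,0,order
lagomorphs,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0,order
carnivores,0,1,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,order
mustelids,0,1,0,1,0,1,2,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,family
bears,0,1,0,1,0,0,1,0,0,0,2,0,0,0,0,0,0,0,0,0,0,0,0,0,0,family
ungulates,0,2,0,1,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,2,0,0,0,0,0,order
cetaceans,0,0,2,1,1,1,0,0,0,0,0,0,0,2,0,0,0,0,2,1,0,0,1,0,0,infraorder
sirenians,0,0,0,2,0,2,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0,order
elephants,0,1,1,1,0,2,1,0,0,0,0,2,0,0,0,0,0,0,1,1,1,0,0,0,0,family
prosimians,0,1,2,1,0,0,2,0,0,1,0,0,0,0,0,0,0,0,1,0,0,0,0,1,0,suborder
NW_monkeys,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,2,2,2,1,1,1,1,0,1,0,parvorder
OW_monkeys,1,1,1,1,2,1,1,2,1,1,1,2,0,2,0,0,0,2,0,0,0,0,0,1,0,family
gibbons,0,1,2,1,0,0,1,2,0,1,0,0,0,0,0,2,0,0,2,0,0,0,0,1,0,family
orangutans,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,2,2,1,1,1,1,1,0,1,0,genus
gorillas,1,1,1,1,2,2,1,2,1,1,1,2,2,2,1,0,0,0,0,0,0,0,0,1,0,genus
chimpanzees,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,2,2,1,1,1,1,1,0,1,0,genus
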