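(((insects,arachnids,crustaceans)arthropoda,(gastropods,cephalopods)mollusca)protostomia,(echinoderms,(fish,(amphibians,((reptiles,birds)sauropsida,(marsupials,((rodents,lagomorphs)glires,((mustelids,bears)carnivores,(((cetaceans,ungulates)cetartiodactyla,(sirenians,elephants)paenungulata)ungulata_clade,(prosimians,(NW_monkeys,(OW_monkeys,(gibbons,(orangutans,(gorillas,chimpanzees)homininae)hominidae_core)hominoidea)catarrhini)simiiformes)primates)boreoeutheria)laurasiatheria_plus)placentalia)theria)amniota)tetrapoda)vertebrata)deuterostomia)animalia;
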