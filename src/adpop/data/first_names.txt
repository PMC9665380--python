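amber
amelia
ana
angela
anna
april
aria
ashley
aurora
autumn
bella
bianca
brandy
brittany
candy
carla
carmen
celine
chanel
chloe
christina
cindy
claire
crystal
daisy
dana
daniela
destiny
diamond
diana
elena
emily
emma
erica
eva
faith
gabriella
gina
grace
hailey
hannah
heather
holly
isabella
ivy
jade
jasmine
jenna
jennifer
jessica
jolene
julia
kayla
keira
kelly
kim
kira
kylie
lana
laura
layla
leah
lena
lexi
lily
linda
lisa
lola
london
lucy
luna
madison
maria
melissa
mercedes
mia
michelle
mimi
monica
monika
natalia
natasha
nicole
nina
olivia
paris
penelope
phoenix
rachel
raven
rebecca
riley
rose
roxy
ruby
sabrina
samantha
sandra
sara
sasha
savannah
scarlett
selena
serena
sierra
sofia
sophie
stella
summer
susan
tara
tiffany
tina
valerie
vanessa
venus
veronica
victoria
violet
vivian
zoe
adam
alex
andre
anthony
austin
blake
brandon
carlos
chris
daniel
david
derek
dylan
eric
ethan
felix
gabriel
james
jason
jayden
jordan
josh
justin
kevin
logan
lucas
marc
marco
mario
mark
matt
max
michael
mike
nathan
nick
noah
oliver
owen
patrick
paul
ryan
sam
sebastian
simon
steve
tony
tristan
tyler
victor
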