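# Fixed neutral filler vocabulary for the synthetic corpus generator.
# 500 words, none of which fires any bundled class rule or keyword.
coffee
tea
morning
evening
afternoon
breakfast
lunch
dinner
kitchen
garden
window
table
chair
sofa
lamp
carpet
mirror
bottle
cup
plate
spoon
fork
knife
oven
fridge
shelf
book
page
chapter
letter
pencil
crayon
notebook
folder
backpack
jacket
coat
scarf
glove
sweater
sock
shoe
boot
umbrella
wallet
ticket
coin
key
lock
gate
fence
yard
street
corner
tunnel
station
platform
carriage
engine
wheel
tyre
pedal
saddle
basket
lane
path
trail
hill
valley
meadow
river
lake
pond
stream
stone
pebble
sand
cliff
beach
wave
tide
shell
seaweed
cloud
breeze
frost
dew
puddle
raincoat
mountain
forest
tree
branch
leaf
root
bark
moss
fern
flower
petal
seed
berry
apple
orange
banana
pear
grape
lemon
melon
cherry
plum
peach
tomato
potato
carrot
onion
pepper
lettuce
cabbage
mushroom
rice
pasta
bread
cheese
butter
honey
jam
sugar
salt
flour
biscuit
cake
muffin
toast
cereal
soup
salad
sandwich
pie
pudding
chocolate
sweetshop
market
shop
bakery
library
museum
cinema
theatre
gallery
park
bench
fountain
statue
clock
tower
roof
chimney
attic
cellar
hallway
stair
ladder
bucket
broom
sponge
towel
blanket
pillow
curtain
cushion
drawer
wardrobe
hanger
hook
nail
hammer
wrench
pliers
tape
ruler
compass
globe
map
atlas
photo
frame
album
camera
lens
tripod
battery
charger
cable
plug
socket
switch
bulb
candle
match
lantern
torch
radio
speaker
headphone
screen
keyboard
mouse
monitor
printer
scanner
paper
envelope
stamp
parcel
package
courier
van
lorry
tractor
trailer
barge
ferry
harbour
dock
anchor
sail
mast
deck
cabin
porthole
compartment
luggage
suitcase
passport
itinerary
journey
voyage
excursion
picnic
campfire
tent
sleepingbag
lanyard
whistle
badge
uniform
apron
helmet
goggles
sneaker
laces
racket
bat
ball
net
hoop
puck
skate
sledge
kite
marble
puzzle
chess
checkers
domino
dice
card
token
board
counter
violin
piano
drum
flute
trumpet
cello
harp
banjo
chord
melody
rhythm
verse
chorus
poem
story
novel
essay
article
journal
diary
calendar
schedule
agenda
meeting
minute
hour
second
week
fortnight
season
spring
summer
autumn
winter
holiday
festival
parade
carnival
fair
circus
magician
juggler
acrobat
clown
puppet
marionette
balloon
confetti
ribbon
banner
poster
sticker
magnet
souvenir
postcard
quiet
calm
gentle
bright
sunny
cloudy
breezy
warm
cool
mild
crisp
fresh
tidy
neat
cosy
plain
simple
round
square
narrow
wide
tall
short
long
brief
early
late
quick
slow
steady
smooth
soft
firm
light
heavy
thin
thick
shiny
dull
pale
vivid
golden
silver
purple
yellow
green
blue
grey
brown
pink
maroon
beige
olive
teal
wooden
metal
plastic
woolen
cotton
silk
velvet
glass
ceramic
rubber
leather
floral
striped
spotted
checked
curly
straight
wavy
tiny
huge
enormous
modest
humble
polite
friendly
cheerful
pleasant
ordinary
usual
common
rare
local
distant
nearby
northern
southern
eastern
western
ancient
modern
classic
vintage
walked
strolled
wandered
rode
cycled
sailed
rowed
painted
sketched
drew
baked
cooked
stirred
mixed
poured
sipped
tasted
smelled
listened
watched
observed
noticed
visited
toured
explored
climbed
hiked
jogged
skipped
danced
hummed
sang
whistled
played
practised
rehearsed
studied
read
wrote
typed
printed
folded
sorted
stacked
arranged
tidied
cleaned
washed
rinsed
dried
ironed
mended
sewed
knitted
planted
watered
pruned
harvested
picked
gathered
collected
traded
bought
sold
counted
measured
weighed
packed
unpacked
wrapped
opened
closed
locked
the
an
this
that
those
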